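"""Decoy-set scoring and ranking performance.

Given a set of alternative structural models (decoys) of one target with
quality labels ("acceptable+" pooling acceptable/medium/high docking
quality versus "incorrect"), every model is scored with a per-model
derived seed and the ranking is summarised by AUROC and Top-N success
rates. The per-chain MSAs are read and paired once per target — only the
contacts differ between decoys — with coverage and gap filters over all
query positions so the pairing is identical for every model.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ZeppiError
from .msa import pair_homodimer, pair_msas, read_msa
from .structure import (
    compute_surface,
    extract_contacts,
    map_structure_to_msa,
    parse_dimer,
)
from .zscore import ScoreConfig, score_paired

ACCEPTABLE = "acceptable+"
INCORRECT = "incorrect"


@dataclass
class DecoyRecord:
    model_id: str
    path: Path
    label: str  # "acceptable+" or "incorrect"


@dataclass
class DecoySet:
    """All decoys of one target share chains and MSAs; poses differ."""

    target_id: str
    records: list[DecoyRecord]
    msa1_file: str | Path
    msa2_file: str | Path | None = None
    chain1: str = "A"
    chain2: str = "B"
    homodimer: bool = False


def read_manifest(path: str | Path, base_dir: str | Path | None = None) -> list[DecoyRecord]:
    """TSV manifest: model_path <tab> label; model_id is the file stem."""
    base = Path(base_dir) if base_dir is not None else Path(path).parent
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        model_path, label = line.split("\t")
        p = Path(model_path)
        if not p.is_absolute():
            p = base / p
        records.append(DecoyRecord(model_id=p.stem, path=p, label=label))
    return records


def model_seed(model_id: str, base_seed: int = 0) -> int:
    """Stable per-model seed: reproducible, decorrelated across decoys."""
    return (base_seed * 1000003 + zlib.crc32(model_id.encode())) % (2**31 - 1)


def score_decoys(
    decoy_set: DecoySet,
    config: ScoreConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """One score per decoy; unscoreable models get a null (NaN) score.

    Returns a DataFrame with columns model_id, zeppi_score, label,
    n_contacts, error (empty string when scored).
    """
    config = config or ScoreConfig()
    msa1 = read_msa(
        decoy_set.msa1_file,
        format=config.msa_format,
        species_regex=config.species_regex,
    )
    if decoy_set.homodimer:
        msa2 = msa1
        pmsa = pair_homodimer(msa1)
    else:
        if decoy_set.msa2_file is None:
            raise ValueError("msa2_file required for heterodimer decoy sets")
        msa2 = read_msa(
            decoy_set.msa2_file,
            format=config.msa_format,
            species_regex=config.species_regex,
        )
        pmsa = pair_msas(msa1, msa2)

    rows = []
    for rec in decoy_set.records:
        seed = model_seed(rec.model_id, base_seed)
        try:
            c1, c2 = parse_dimer(rec.path, decoy_set.chain1, decoy_set.chain2)
            smap1, smap2 = compute_surface(
                c1,
                c2,
                probe_radius=config.probe_radius,
                rel_asa_threshold=config.rel_asa_threshold,
            )
            contacts = extract_contacts(c1, c2, cutoff=config.contact_cutoff)
            map1 = map_structure_to_msa(
                c1, msa1.query_sequence, config.min_identity
            )
            map2 = map_structure_to_msa(
                c2, msa2.query_sequence, config.min_identity
            )
            result = score_paired(
                pmsa,
                smap1,
                smap2,
                contacts,
                map1,
                map2,
                config,
                seed=seed,
                model_id=rec.model_id,
                homodimer=decoy_set.homodimer,
            )
            rows.append(
                {
                    "model_id": rec.model_id,
                    "zeppi_score": result.report.zeppi_score,
                    "label": rec.label,
                    "n_contacts": result.report.n_contacts,
                    "error": "",
                }
            )
        except ZeppiError as exc:
            rows.append(
                {
                    "model_id": rec.model_id,
                    "zeppi_score": np.nan,
                    "label": rec.label,
                    "n_contacts": 0,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


def ranking_metrics(
    scores: pd.DataFrame, top_n: tuple[int, ...] = (1, 5, 100)
) -> dict:
    """AUROC (rank statistic, ties averaged) and Top-N success rates.

    Unscoreable rows (NaN score) are excluded and counted. success@N is
    1 when any acceptable+ decoy appears among the N highest scores
    (ties broken deterministically on model_id); AUROC is None when only
    one label class is present.
    """
    valid = scores.dropna(subset=["zeppi_score"]).copy()
    n_excluded = len(scores) - len(valid)
    pos = valid["label"] == ACCEPTABLE
    auroc = None
    if pos.any() and (~pos).any():
        ranks = rankdata(valid["zeppi_score"].to_numpy())  # ties averaged
        n_pos = int(pos.sum())
        n_neg = len(valid) - n_pos
        u = ranks[pos.to_numpy()].sum() - n_pos * (n_pos + 1) / 2
        auroc = float(u / (n_pos * n_neg))
    ordered = valid.sort_values(
        ["zeppi_score", "model_id"], ascending=[False, True]
    )
    success = {
        f"success@{n}": int(
            (ordered["label"].head(n) == ACCEPTABLE).any()
        )
        for n in top_n
    }
    return {
        "auroc": auroc,
        **success,
        "n_scored": len(valid),
        "n_excluded": n_excluded,
    }
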