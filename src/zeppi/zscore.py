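"""Permutation null and final interface Z-scores.

The significance of an interface's metric panel is judged against fake
interfaces: for each sample, every interfacial residue of a chain is
replaced (injectively) by a randomly drawn non-interface surface residue
of the same chain, and the real contact topology is carried through the
substitution. One hundred such interfaces give the null mean and
standard deviation of each of the twelve metrics; the Z-score of a
metric is the larger of its raw and APC-corrected Z, and the final score
of the model is the maximum over metrics.

When a chain has more interface residues than spare surface residues the
sampling pool widens to all non-interface residues (buried included),
matching the intended fallback for small proteins.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InterfaceTooLargeError, UnscoreableModelError
from .metrics import MetricPanel, METRIC_KEYS, metric_panel
from .msa import (
    DEFAULT_SPECIES_REGEX,
    PairedMSA,
    pair_homodimer,
    pair_msas,
    read_msa,
)
from .structure import (
    ChainStructure,
    DEFAULT_CONTACT_CUTOFF,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_REL_ASA,
    InterfaceContacts,
    ResKey,
    SurfaceMap,
    compute_surface,
    extract_contacts,
    map_structure_to_msa,
    parse_dimer,
    require_contacts,
)

Z_CAP = 99.0
SHALLOW_MSA_DEPTH = 10


@dataclass
class ScoreConfig:
    """Tunable parameters of the scoring pipeline."""

    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    rel_asa_threshold: float = DEFAULT_REL_ASA
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_samples: int = 100
    use_dca: bool | None = None  # None: homodimers only
    dca_lambda: float = 0.5
    msa_format: str = "fasta"
    species_regex: str = DEFAULT_SPECIES_REGEX
    min_identity: float = 0.30
    z_cap: float = Z_CAP


@dataclass
class FakeInterface:
    """One null sample: per-chain residue substitutions and the induced
    contact list (same topology as the real interface)."""

    sub1: dict[ResKey, ResKey]
    sub2: dict[ResKey, ResKey]
    contacts: list[tuple[ResKey, ResKey]]


@dataclass
class MetricScore:
    """Null comparison for a single metric (one of the 12)."""

    real: float
    null_mean: float
    null_sd: float
    z: float
    degenerate: bool = False


@dataclass
class ZeppiReport:
    """Full per-model report: 12 metric Z-scores and the final score."""

    model_id: str
    n_msa: int
    n_contacts: int
    seed: int
    metrics: dict[str, MetricScore]
    z_combined: dict[str, float]  # per base metric x aggregator: max(raw, apc)
    zeppi_score: float
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def to_tsv_row(self) -> pd.DataFrame:
        row: dict[str, object] = {
            "model_id": self.model_id,
            "n_msa": self.n_msa,
            "n_contacts": self.n_contacts,
        }
        for key in METRIC_KEYS:
            ms = self.metrics.get(key)
            row[f"z_{key}"] = ms.z if ms is not None else np.nan
        row["zeppi_score"] = self.zeppi_score
        row["seed"] = self.seed
        return pd.DataFrame([row])


@dataclass
class ScoreResult:
    """Report plus the panels behind it, for diagnostics and calibration."""

    report: ZeppiReport
    real_panel: MetricPanel
    null_panels: list[MetricPanel]
    paired_msa: PairedMSA
    contacts: InterfaceContacts


def _null_pool(
    smap: SurfaceMap,
    iface: set[ResKey],
    allowed: set[ResKey] | None,
) -> list[ResKey]:
    def ok(k: ResKey) -> bool:
        return k not in iface and (allowed is None or k in allowed)

    surface_pool = [
        k for k, s in zip(smap.res_keys, smap.is_surface) if s and ok(k)
    ]
    if len(surface_pool) >= len(iface):
        return surface_pool
    # fallback: the whole chain outside the interface, buried included
    full_pool = [k for k in smap.res_keys if ok(k)]
    if len(full_pool) < len(iface):
        raise InterfaceTooLargeError(
            "interface too large to null-sample: "
            f"{len(iface)} interface residues, {len(full_pool)} candidates"
        )
    return full_pool


def sample_fake_interfaces(
    surface_map1: SurfaceMap,
    surface_map2: SurfaceMap,
    contacts: InterfaceContacts,
    n_samples: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    allowed1: set[ResKey] | None = None,
    allowed2: set[ResKey] | None = None,
) -> list[FakeInterface]:
    """Draw seeded fake interfaces preserving the real contact topology.

    Per sample and per chain, a uniform injective map from the
    interfacial residues into that chain's non-interface surface pool
    (or, if too small, all non-interface residues). ``allowed`` sets
    restrict pools to residues that can actually be scored (mapped to
    retained MSA columns).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    iface1 = list(contacts.iface1)
    iface2 = list(contacts.iface2)
    pool1 = _null_pool(surface_map1, set(iface1), allowed1)
    pool2 = _null_pool(surface_map2, set(iface2), allowed2)
    fakes = []
    for _ in range(n_samples):
        pick1 = rng.choice(len(pool1), size=len(iface1), replace=False)
        pick2 = rng.choice(len(pool2), size=len(iface2), replace=False)
        sub1 = {r: pool1[int(i)] for r, i in zip(iface1, pick1)}
        sub2 = {r: pool2[int(i)] for r, i in zip(iface2, pick2)}
        fakes.append(
            FakeInterface(
                sub1=sub1,
                sub2=sub2,
                contacts=[(sub1[a], sub2[b]) for a, b in contacts.contacts],
            )
        )
    return fakes


def zscore_panel(
    real: MetricPanel,
    null_panels: list[MetricPanel],
    model_id: str = "",
    n_msa: int = 0,
    seed: int = 0,
    z_cap: float = Z_CAP,
    warnings_list: list[str] | None = None,
) -> ZeppiReport:
    """Z-scores of the 12 metrics against their fake-interface nulls.

    z = (real - mean(null)) / sd(null) with the population standard
    deviation; a degenerate null (sd = 0) yields z = 0 when the real
    value equals the constant, otherwise a signed cap of +/-99.
    """
    if len(null_panels) < 2:
        raise ValueError("need at least 2 null panels")
    metrics: dict[str, MetricScore] = {}
    for key in METRIC_KEYS:
        r = real.values.get(key)
        if r is None or not np.isfinite(r):
            continue
        null_vals = np.array(
            [
                p.values[key]
                for p in null_panels
                if p.values.get(key) is not None
                and np.isfinite(p.values[key])
            ]
        )
        if len(null_vals) < 2:
            continue
        mu = float(null_vals.mean())
        sd = float(null_vals.std())  # population sd over the samples
        degenerate = sd == 0.0
        if degenerate:
            z = 0.0 if abs(r - mu) < 1e-12 else float(np.sign(r - mu)) * z_cap
        else:
            z = (r - mu) / sd
        metrics[key] = MetricScore(
            real=float(r), null_mean=mu, null_sd=sd, z=z, degenerate=degenerate
        )
    if not metrics:
        raise UnscoreableModelError("all null panels unscoreable")
    z_combined: dict[str, float] = {}
    for m in ("mi", "con", "dca"):
        for agg in ("mean", "top"):
            zs = [
                metrics[f"{m}_{agg}_{form}"].z
                for form in ("raw", "apc")
                if f"{m}_{agg}_{form}" in metrics
            ]
            if zs:
                z_combined[f"{m}_{agg}"] = max(zs)
    return ZeppiReport(
        model_id=model_id,
        n_msa=n_msa,
        n_contacts=real.n_contacts,
        seed=seed,
        metrics=metrics,
        z_combined=z_combined,
        zeppi_score=max(z_combined.values()),
        warnings=list(warnings_list or []),
    )


def _mapped_positions(
    mapping: dict[ResKey, int],
    smap: SurfaceMap,
    iface: list[ResKey],
) -> set[int]:
    """Query positions of surface or interfacial residues (pair scope)."""
    scoped = set(iface)
    scoped.update(smap.surface_residues())
    return {mapping[k] for k in scoped if k in mapping}


def score_paired(
    paired_msa: PairedMSA,
    surface_map1: SurfaceMap,
    surface_map2: SurfaceMap,
    contacts: InterfaceContacts,
    map1: dict[ResKey, int],
    map2: dict[ResKey, int],
    config: ScoreConfig,
    seed: int = 0,
    model_id: str = "",
    homodimer: bool = False,
) -> ScoreResult:
    """Score an interface against an already-paired MSA."""
    require_contacts(contacts)
    warnings_list: list[str] = []

    def cols_of(pair: tuple[ResKey, ResKey]) -> tuple[int, int] | None:
        a, b = pair
        qa, qb = map1.get(a), map2.get(b)
        if qa is None or qb is None:
            return None
        if not (
            paired_msa.is_retained(1, qa) and paired_msa.is_retained(2, qb)
        ):
            return None
        return paired_msa.column_index(1, qa), paired_msa.column_index(2, qb)

    scored: list[tuple[ResKey, ResKey]] = []
    contact_cols: list[tuple[int, int]] = []
    for pair in contacts.contacts:
        cc = cols_of(pair)
        if cc is None:
            continue
        scored.append(pair)
        contact_cols.append(cc)
    n_dropped = contacts.n_contacts - len(scored)
    if n_dropped:
        warnings_list.append(
            f"{n_dropped} contact(s) dropped: unmapped or gap-filtered columns"
        )
    if not scored:
        raise UnscoreableModelError(
            "unscoreable model: no contact maps to retained MSA columns"
        )
    scored_contacts = InterfaceContacts(contacts=scored)
    use_dca = config.use_dca if config.use_dca is not None else homodimer

    real_panel = metric_panel(
        paired_msa,
        contact_cols,
        use_dca=use_dca,
        dca_lambda=config.dca_lambda,
    )

    def allowed(mapping: dict[ResKey, int], protein: int) -> set[ResKey]:
        return {
            k
            for k, q in mapping.items()
            if paired_msa.is_retained(protein, q)
        }

    fakes = sample_fake_interfaces(
        surface_map1,
        surface_map2,
        scored_contacts,
        n_samples=config.n_samples,
        seed=seed,
        allowed1=allowed(map1, 1),
        allowed2=allowed(map2, 2),
    )
    null_panels = []
    for fake in fakes:
        cols = [
            (
                paired_msa.column_index(1, map1[a]),
                paired_msa.column_index(2, map2[b]),
            )
            for a, b in fake.contacts
        ]
        null_panels.append(
            metric_panel(
                paired_msa,
                cols,
                use_dca=use_dca,
                dca_lambda=config.dca_lambda,
            )
        )
    if paired_msa.n_msa < SHALLOW_MSA_DEPTH:
        warnings_list.append(
            f"shallow paired MSA: depth {paired_msa.n_msa}"
        )
    report = zscore_panel(
        real_panel,
        null_panels,
        model_id=model_id,
        n_msa=paired_msa.n_msa,
        seed=seed,
        z_cap=config.z_cap,
        warnings_list=warnings_list,
    )
    return ScoreResult(
        report=report,
        real_panel=real_panel,
        null_panels=null_panels,
        paired_msa=paired_msa,
        contacts=scored_contacts,
    )


def score_model_detailed(
    structure_file: str | Path,
    chain1: str,
    chain2: str,
    msa1_file: str | Path,
    msa2_file: str | Path | None = None,
    homodimer: bool = False,
    config: ScoreConfig | None = None,
    seed: int = 0,
    model_id: str | None = None,
) -> ScoreResult:
    """End-to-end scoring of one dimer model; returns panels as well."""
    config = config or ScoreConfig()
    if not homodimer and msa2_file is None:
        raise ValueError("msa2_file required unless homodimer=True")
    model_id = model_id or Path(structure_file).stem

    c1, c2 = parse_dimer(structure_file, chain1, chain2)
    smap1, smap2 = compute_surface(
        c1,
        c2,
        probe_radius=config.probe_radius,
        rel_asa_threshold=config.rel_asa_threshold,
    )
    contacts = require_contacts(
        extract_contacts(c1, c2, cutoff=config.contact_cutoff)
    )
    msa1 = read_msa(
        msa1_file, format=config.msa_format, species_regex=config.species_regex
    )
    msa2 = (
        msa1
        if homodimer
        else read_msa(
            msa2_file,
            format=config.msa_format,
            species_regex=config.species_regex,
        )
    )
    map1 = map_structure_to_msa(c1, msa1.query_sequence, config.min_identity)
    map2 = map_structure_to_msa(c2, msa2.query_sequence, config.min_identity)
    pos1 = _mapped_positions(map1, smap1, contacts.iface1)
    pos2 = _mapped_positions(map2, smap2, contacts.iface2)
    if homodimer:
        pmsa = pair_homodimer(msa1, surface=pos1 | pos2)
    else:
        pmsa = pair_msas(msa1, msa2, surface1=pos1, surface2=pos2)
    return score_paired(
        pmsa,
        smap1,
        smap2,
        contacts,
        map1,
        map2,
        config,
        seed=seed,
        model_id=model_id,
        homodimer=homodimer,
    )


def score_model(
    structure_file: str | Path,
    chain1: str,
    chain2: str,
    msa1_file: str | Path,
    msa2_file: str | Path | None = None,
    homodimer: bool = False,
    config: ScoreConfig | None = None,
    seed: int = 0,
    model_id: str | None = None,
) -> ZeppiReport:
    """Score one structural model of a dimer; the main entry point."""
    return score_model_detailed(
        structure_file,
        chain1,
        chain2,
        msa1_file,
        msa2_file,
        homodimer=homodimer,
        config=config,
        seed=seed,
        model_id=model_id,
    ).report
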