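"""Score a toy dimer whose interface carries planted covariation.

Builds a seeded synthetic problem — a two-chain model with four true
contacts and a pair of species-matched MSAs in which the contact columns
covary perfectly — and scores it end to end. The final score is the
maximum Z-score over the interface metrics against 100 fake interfaces;
values above ~3 indicate an evolutionary signal supporting the modelled
interface.
"""
import tempfile
from pathlib import Path

from zeppi import FixtureSpec, make_paired_fixture_msas, score_model, write_toy_dimer

with tempfile.TemporaryDirectory() as tmp:
    work = Path(tmp)
    spec = FixtureSpec(seed=7, fidelity=1.0, msa_depth=500)
    pdb = write_toy_dimer(spec, work / "dimer.pdb")
    msa1, msa2 = make_paired_fixture_msas(spec, work)

    report = score_model(pdb, "A", "B", msa1, msa2, seed=1)

print(f"model: {report.model_id}")
print(f"paired MSA depth (N_MSA): {report.n_msa}")
print(f"scored contacts: {report.n_contacts}")
for key, ms in sorted(report.metrics.items()):
    print(f"  {key:14s} real={ms.real:8.4f} null={ms.null_mean:8.4f}"
          f" +/- {ms.null_sd:7.4f}  z={ms.z:9.2f}")
print(f"final score (max over metrics): {report.zeppi_score:.2f}")
print("-> a score this far above 3 means the interface columns coevolve"
      " far beyond what random surface residues show.")
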