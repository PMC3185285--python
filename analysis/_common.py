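"""Shared plumbing for the numbered analysis drivers: one canonical
synthetic study (focal-set TE effects switched on) under results/study."""

from pathlib import Path

from tephylo import synth
from tephylo.synth import SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
STUDY_DIR = RESULTS / "study"

#: The canonical synthetic study: TE depresses omega in the focal set at
#: -0.02 per Mb and sharpens its codon bias at -0.5 ENC per Mb; controls
#: carry no TE effect.  Master seed 20110914.
STUDY_CONFIG = SimConfig(
    seed=20110914,
    slope_pirna=-0.02,
    enc_slope_pirna=-0.5,
    with_sequences=True,
    n_codons=400,
)


def ensure_study() -> Path:
    if not (STUDY_DIR / "traits.tsv").exists():
        synth.write_study(synth.simulate_study(STUDY_CONFIG), STUDY_DIR)
    return STUDY_DIR
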