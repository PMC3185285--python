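"""Codon-usage statistics: CDS hygiene, codon counting, Wright's effective
number of codons (ENC) and GC content at third positions (GC3).

ENC ranges from 20 (one codon per amino acid, maximal bias) to 61 (uniform
synonymous usage).  The estimator follows Wright: within each amino-acid
family with k synonymous codons and n >= 2 observed codons the codon
homozygosity is F = (n * sum(p_i^2) - 1) / (n - 1); F values are averaged
within degeneracy classes and ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at
61.  Met and Trp contribute the constant 2.  If the 3-fold class (Ile) is
unusable its homozygosity is imputed as (F2 + F4)/2; any other missing class
leaves ENC undefined.

The genetic code is the standard nuclear code throughout.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CodonUsageError",
    "ENCUndefinedError",
    "CodonCounts",
    "CodonBiasSummary",
    "SENSE_CODONS",
    "SYNONYMOUS_FAMILIES",
    "clean_cds",
    "count_codons",
    "enc",
    "enc_from_probs",
    "gc3",
    "codon_bias_summary",
    "read_cds_fasta",
    "codon_bias_table",
]


class CodonUsageError(ValueError):
    """Unusable coding sequence or codon counts."""


class ENCUndefinedError(CodonUsageError):
    """ENC cannot be computed (an entire degeneracy class is unusable)."""


def _standard_families() -> dict[str, tuple[str, ...]]:
    table = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
    fam: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fam.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cods)) for aa, cods in fam.items()}


SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = _standard_families()
STOP_CODONS: frozenset = frozenset(
    CodonTable.unambiguous_dna_by_id[1].stop_codons
)
SENSE_CODONS: tuple = tuple(
    sorted(c for cods in SYNONYMOUS_FAMILIES.values() for c in cods)
)
# degeneracy classes and the number of families Wright's formula expects
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass(frozen=True)
class CodonCounts:
    counts: Mapping[str, int]

    def __post_init__(self):
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise CodonUsageError(f"non-sense codons in counts: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise CodonUsageError("negative codon counts")

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class CodonBiasSummary:
    enc: float
    gc3: float
    n_codons: int


def clean_cds(seq: str) -> list[str]:
    """Split an in-frame nucleotide sequence into codons, dropping any
    triplet containing a non-ACGT character, a trailing incomplete triplet,
    and (with a warning) internal stop codons.  The frame of retained
    triplets is preserved."""
    s = str(seq).upper().replace("U", "T")
    codons = []
    n_stop = 0
    for i in range(0, len(s) - len(s) % 3, 3):
        cod = s[i : i + 3]
        if any(ch not in "ACGT" for ch in cod):
            continue
        if cod in STOP_CODONS:
            n_stop += 1
            continue
        codons.append(cod)
    if n_stop:
        warnings.warn(
            f"dropped {n_stop} internal stop codon(s)", UserWarning, stacklevel=2
        )
    if not codons:
        raise CodonUsageError("no usable codons")
    return codons


def count_codons(codons: Sequence[str]) -> CodonCounts:
    return CodonCounts(counts=dict(Counter(codons)))


def _family_F(counts: Mapping[str, int], family: Sequence[str]) -> tuple[float, int] | None:
    n = sum(counts.get(c, 0) for c in family)
    if n < 2:
        return None
    sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in family)
    return (n * sum_p2 - 1.0) / (n - 1.0), n


def enc(counts: CodonCounts | Mapping[str, int]) -> float:
    """Wright's effective number of codons from observed codon counts."""
    if isinstance(counts, CodonCounts):
        counts = counts.counts
    class_F: dict[int, list[float]] = {k: [] for k in _CLASS_SIZES}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        k = len(family)
        if k == 1:
            continue
        res = _family_F(counts, family)
        if res is not None:
            class_F[k].append(res[0])
    means: dict[int, float] = {}
    for k, fs in class_F.items():
        if fs:
            means[k] = sum(fs) / len(fs)
    for k in (2, 4, 6):
        if k not in means or means[k] <= 0.0:
            raise ENCUndefinedError(
                f"the {k}-fold degeneracy class is unusable; ENC undefined"
            )
    if 3 not in means or means[3] <= 0.0:
        means[3] = (means[2] + means[4]) / 2.0  # Wright's imputation for Ile
    nc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(nc, 61.0)


def enc_from_probs(probs: Mapping[str, float]) -> float:
    """ENC under known within-family codon probabilities (the large-n limit,
    with F = sum p_i^2 per family).  Used for calibrating simulated codon
    usage and in asymptotic invariance checks."""
    means: dict[int, float] = {}
    for k in _CLASS_SIZES:
        fs = []
        for aa, family in SYNONYMOUS_FAMILIES.items():
            if len(family) != k:
                continue
            tot = sum(probs.get(c, 0.0) for c in family)
            if tot <= 0:
                continue
            fs.append(sum((probs.get(c, 0.0) / tot) ** 2 for c in family))
        if fs:
            means[k] = sum(fs) / len(fs)
    for k in (2, 4, 6):
        if k not in means or means[k] <= 0.0:
            raise ENCUndefinedError(
                f"the {k}-fold degeneracy class is unusable; ENC undefined"
            )
    if 3 not in means or means[3] <= 0.0:
        means[3] = (means[2] + means[4]) / 2.0
    nc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(nc, 61.0)


def gc3(codons: Sequence[str]) -> float:
    """Fraction of retained sense codons whose third position is G or C."""
    if len(codons) == 0:
        raise CodonUsageError("zero codons: GC3 undefined")
    return sum(1 for c in codons if c[2] in "GC") / len(codons)


def codon_bias_summary(seq: str) -> CodonBiasSummary:
    codons = clean_cds(seq)
    return CodonBiasSummary(
        enc=enc(count_codons(codons)), gc3=gc3(codons), n_codons=len(codons)
    )


def read_cds_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA of in-frame coding sequences, keyed by
    record id."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    return out


def codon_bias_table(fasta_dir, genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-gene, per-species codon-bias table from a directory of FASTA
    files (one file per gene, record ids = species).  Columns: gene,
    species, n_codons, enc, gc3, length_aa (= retained codon count, the
    gene-length regression covariate)."""
    fasta_dir = Path(fasta_dir)
    files = sorted(fasta_dir.glob("*.fasta")) + sorted(fasta_dir.glob("*.fa"))
    if genes is not None:
        wanted = set(genes)
        files = [f for f in files if f.stem in wanted]
    rows = []
    for f in files:
        for species, seq in read_cds_fasta(f).items():
            s = codon_bias_summary(seq)
            rows.append(
                {
                    "gene": f.stem,
                    "species": species,
                    "n_codons": s.n_codons,
                    "enc": s.enc,
                    "gc3": s.gc3,
                    "length_aa": s.n_codons,
                }
            )
    if not rows:
        raise CodonUsageError(f"no FASTA records found under {fasta_dir}")
    return pd.DataFrame(rows)
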