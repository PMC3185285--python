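"""Synthetic studies with the statistical structure the analysis assumes.

The generator emulates the study design end-to-end so every pipeline stage is
testable with known ground truth:

* a fixed tree (the 12-species study tree) or a simulated pure-birth tree;
* a per-species TE-abundance trait (Mb) evolving as geometric Brownian
  motion (BM on the log scale), so abundances stay positive with a
  realistic 10-40 Mb spread around ~20 Mb;
* a panel of focal ("piRNA") and control genes whose response trait
  (omega-like, or ENC-like) is a linear function of TE abundance with a
  set-specific slope plus Brownian noise on the tree;
* optional in-frame coding sequences per gene and species whose codon-usage
  sharpness is calibrated by bisection so the expected ENC hits a target
  that may itself be coupled to TE abundance.

Everything is deterministic given the master seed; per-gene streams are
derived by hashing (seed, gene id) so reordering the gene list does not
change the data.  Ground truth (all generating parameters) is stored with
the study.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import codonstats
from .matching import stable_seed
from .phylo import Phylogeny, apply_lambda, parse_newick

__all__ = [
    "SynthError",
    "SimConfig",
    "SyntheticStudy",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_codon_sequence",
    "simulate_study",
    "write_study",
    "read_study",
]


class SynthError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-generation parameters (defaults are the study conditions).

    TE abundance: log-BM with root ln(20 Mb) and rate 0.25 per unit branch
    length, giving a tip SD of ~0.4 on the log scale on the study tree
    (roughly 10-40 Mb, the span of euchromatic repeat content across the
    twelve genomes).  Response traits: per-gene intercept plus a set-specific
    slope on TE (Mb) plus BM noise with tip SD ~0.05 for the omega-like
    trait and ~3 ENC units for the codon-bias trait.
    """

    seed: int
    tree_source: str = "study"        # "study" | "pure-birth"
    n_tips: int = 12
    birth_rate: float = 1.0
    lambda_true: float = 1.0
    directional_slope: float = 0.0    # drift of trait mean per unit path length
    # TE trait (geometric BM)
    te_log_mean: float = math.log(20.0)
    te_log_rate: float = 0.25         # BM rate on log TE per unit branch length
    # gene panel
    n_pirna: int = 11
    n_control: int = 11
    omega_base: float = 0.15
    omega_gene_sd: float = 0.03       # between-gene spread of intercepts
    omega_bm_rate: float = 0.004      # BM noise rate for omega (tip SD ~0.05)
    slope_pirna: float = 0.0          # d omega / d TE (per Mb), focal set
    slope_control: float = 0.0
    # ENC-like trait
    enc_base: float = 45.0
    enc_gene_sd: float = 2.0
    enc_bm_rate: float = 12.0         # tip SD ~3 ENC units
    enc_slope_pirna: float = 0.0      # d ENC / d TE (per Mb), focal set
    enc_slope_control: float = 0.0
    # coding sequences
    with_sequences: bool = False
    n_codons: int = 400

    def __post_init__(self):
        if self.seed is None:
            raise SynthError("a master seed is mandatory")
        if self.n_pirna < 1 or self.n_control < 1:
            raise SynthError("panel sizes must be >= 1")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise SynthError("lambda_true must lie in [0, 1]")


@dataclass
class SyntheticStudy:
    tree: Phylogeny
    te: pd.Series                     # Mb by species
    panel: pd.DataFrame               # long: gene, set, species, omega, enc
    sequences: dict                   # gene -> {species: cds} (may be empty)
    truth: dict                       # generating parameters


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with exponential waiting times; tips are
    labeled t1..tn.  Deterministic given the seed."""
    if n_tips < 3:
        raise SynthError("need at least 3 tips")
    from dendropy.simulate import treesim

    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the process stops at the n-th birth, leaving that cherry with
    # zero-length tips; extend every extant lineage by the waiting time to
    # the next (censored) event so all terminal branches are positive
    extra = rng.expovariate(birth_rate * n_tips)
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{k}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return parse_newick(tree.as_string(schema="newick").strip())


def simulate_bm_traits(
    tree: Phylogeny,
    Sigma,
    lam: float = 1.0,
    alphas=None,
    directional_slopes=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw tip values of p correlated traits from the matrix-normal model:
    row covariance apply_lambda(bm_covariance, lam), column covariance Sigma,
    mean per tip = alpha + slope * root-to-tip length."""
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    p = Sigma.shape[0]
    eigval, eigvec = np.linalg.eigh(Sigma)
    if eigval.min() < -1e-10 * max(eigval.max(), 1.0):
        raise SynthError("Sigma must be positive semi-definite")
    S_half = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None))) @ eigvec.T
    alphas = np.zeros(p) if alphas is None else np.asarray(alphas, dtype=float)
    slopes = (
        np.zeros(p)
        if directional_slopes is None
        else np.asarray(directional_slopes, dtype=float)
    )
    V = apply_lambda(tree.bm_covariance(), lam).to_numpy()
    n = V.shape[0]
    # V is PSD; add a relative jitter only if the factorization needs it
    jitter = 0.0
    scale = float(np.trace(V)) / n
    for _ in range(6):
        try:
            L = np.linalg.cholesky(V + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12 * scale)
    else:  # pragma: no cover
        raise SynthError("tip covariance could not be factorized")
    rng = np.random.default_rng(int(seed))
    Z = rng.standard_normal((n, p))
    rtl = tree.root_to_tip_lengths().to_numpy()
    M = alphas[None, :] + rtl[:, None] * slopes[None, :]
    Y = M + L @ Z @ S_half.T
    return pd.DataFrame(
        Y, index=tree.tip_labels, columns=[f"trait{j+1}" for j in range(p)]
    )


# ---------------------------------------------------------------------------
# codon sequences
# ---------------------------------------------------------------------------

_DEGENERATE_AA = sorted(
    aa for aa, fam in codonstats.SYNONYMOUS_FAMILIES.items() if len(fam) > 1
)
_SINGLE_AA = sorted(
    aa for aa, fam in codonstats.SYNONYMOUS_FAMILIES.items() if len(fam) == 1
)


def _family_probs(sharpness: float) -> dict[str, float]:
    """Within-family codon probabilities with usage weight exp(-s * rank)."""
    probs: dict[str, float] = {}
    for fam in codonstats.SYNONYMOUS_FAMILIES.values():
        w = np.exp(-sharpness * np.arange(len(fam)))
        w = w / w.sum()
        for codon, pi in zip(fam, w):
            probs[codon] = float(pi)
    return probs


def expected_enc(sharpness: float) -> float:
    return codonstats.enc_from_probs(_family_probs(sharpness))


def _calibrate_sharpness(target_enc: float) -> float:
    if not 20.0 < target_enc <= 61.0:
        raise SynthError(f"target ENC must lie in (20, 61], got {target_enc}")
    lo, hi = 0.0, 60.0
    if expected_enc(hi) > target_enc:
        raise SynthError(f"target ENC {target_enc} unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_enc(mid) >= target_enc:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def simulate_codon_sequence(
    target_enc: float, n_codons: int, seed: int = 0
) -> str:
    """An in-frame, stop-free coding sequence whose within-family codon
    usage is calibrated so the expected ENC equals *target_enc*.

    Amino-acid composition: uniform over the 18 degenerate amino acids, with
    Met and Trp at 5% total (so every ENC degeneracy class is exercised).
    """
    if n_codons < 1:
        raise SynthError("n_codons must be positive")
    sharp = _calibrate_sharpness(target_enc)
    probs = _family_probs(sharp)
    rng = np.random.default_rng(int(seed))
    aa_pool = _DEGENERATE_AA + _SINGLE_AA
    aa_p = np.array(
        [0.95 / len(_DEGENERATE_AA)] * len(_DEGENERATE_AA)
        + [0.05 / len(_SINGLE_AA)] * len(_SINGLE_AA)
    )
    aas = rng.choice(len(aa_pool), size=n_codons, p=aa_p)
    out = []
    for k in aas:
        fam = codonstats.SYNONYMOUS_FAMILIES[aa_pool[k]]
        w = np.array([probs[c] for c in fam])
        out.append(fam[rng.choice(len(fam), p=w / w.sum())])
    return "".join(out)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def _study_tree() -> Phylogeny:
    from .datasets import study_tree

    return study_tree()


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a complete synthetic study: tree, TE trait, gene panel with
    omega-like and ENC-like responses, and (optionally) coding sequences."""
    if config.tree_source == "study":
        tree = _study_tree()
    elif config.tree_source == "pure-birth":
        tree = simulate_tree(
            config.n_tips, config.birth_rate, stable_seed(config.seed, "tree")
        )
    else:
        raise SynthError(f"unknown tree source: {config.tree_source!r}")
    tips = tree.tip_labels

    log_te = simulate_bm_traits(
        tree,
        Sigma=[[config.te_log_rate]],
        lam=config.lambda_true,
        alphas=[config.te_log_mean],
        directional_slopes=[config.directional_slope],
        seed=stable_seed(config.seed, "te"),
    ).iloc[:, 0]
    te = np.exp(log_te).rename("te_mb")
    te_centered = te - te.mean()

    genes = [(f"pi{k:02d}", "piRNA") for k in range(1, config.n_pirna + 1)] + [
        (f"ctl{k:02d}", "control") for k in range(1, config.n_control + 1)
    ]
    slope_omega = {"piRNA": config.slope_pirna, "control": config.slope_control}
    slope_enc = {
        "piRNA": config.enc_slope_pirna,
        "control": config.enc_slope_control,
    }

    rows = []
    sequences: dict[str, dict[str, str]] = {}
    for gene, gset in genes:
        grng = np.random.default_rng(stable_seed(config.seed, "gene", gene))
        a_omega = config.omega_base + config.omega_gene_sd * grng.standard_normal()
        a_enc = config.enc_base + config.enc_gene_sd * grng.standard_normal()
        noise = simulate_bm_traits(
            tree,
            Sigma=np.diag([config.omega_bm_rate, config.enc_bm_rate]),
            lam=config.lambda_true,
            seed=stable_seed(config.seed, "noise", gene),
        )
        omega = a_omega + slope_omega[gset] * te_centered + noise.iloc[:, 0]
        enc_trait = a_enc + slope_enc[gset] * te_centered + noise.iloc[:, 1]
        enc_trait = enc_trait.clip(lower=20.5, upper=61.0)
        for sp in tips:
            rows.append(
                {
                    "gene": gene,
                    "set": gset,
                    "species": sp,
                    "omega": float(omega[sp]),
                    "enc": float(enc_trait[sp]),
                }
            )
        if config.with_sequences:
            sequences[gene] = {
                sp: simulate_codon_sequence(
                    float(enc_trait[sp]),
                    config.n_codons,
                    seed=stable_seed(config.seed, "seq", gene, sp),
                )
                for sp in tips
            }

    panel = pd.DataFrame(rows)
    truth = {"config": asdict(config), "te_mean_mb": float(te.mean())}
    return SyntheticStudy(
        tree=tree, te=te, panel=panel, sequences=sequences, truth=truth
    )


def write_study(study: SyntheticStudy, outdir) -> Path:
    """Write a study directory in the formats the pipeline reads: Newick
    tree, TSV trait tables, per-gene FASTA, and a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(study.tree.to_newick() + "\n")
    study.te.rename_axis("species").reset_index().to_csv(
        outdir / "te_abundance.tsv", sep="\t", index=False
    )
    study.panel.to_csv(outdir / "traits.tsv", sep="\t", index=False)
    if study.sequences:
        seqdir = outdir / "sequences"
        seqdir.mkdir(exist_ok=True)
        for gene, recs in study.sequences.items():
            with open(seqdir / f"{gene}.fasta", "w") as fh:
                for sp, seq in recs.items():
                    fh.write(f">{sp}\n{seq}\n")
    (outdir / "ground_truth.json").write_text(
        json.dumps(study.truth, indent=2, sort_keys=True) + "\n"
    )
    return outdir


def read_study(indir) -> SyntheticStudy:
    indir = Path(indir)
    tree = parse_newick((indir / "tree.nwk").read_text().strip())
    te = (
        pd.read_csv(indir / "te_abundance.tsv", sep="\t")
        .set_index("species")["te_mb"]
    )
    panel = pd.read_csv(indir / "traits.tsv", sep="\t")
    sequences: dict[str, dict[str, str]] = {}
    seqdir = indir / "sequences"
    if seqdir.is_dir():
        for f in sorted(seqdir.glob("*.fasta")):
            sequences[f.stem] = codonstats.read_cds_fasta(f)
    truth = {}
    gt = indir / "ground_truth.json"
    if gt.exists():
        truth = json.loads(gt.read_text())
    return SyntheticStudy(
        tree=tree, te=te, panel=panel, sequences=sequences, truth=truth
    )
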