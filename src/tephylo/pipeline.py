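"""Stage-by-stage orchestration of the full analysis.

A *study directory* holds the declared file interfaces: ``tree.nwk``
(Newick), ``te_abundance.tsv`` (species, te_mb), ``traits.tsv`` (long
format: gene, set, species, omega[, dn, ds, enc, ...]) and optionally
``sequences/<gene>.fasta`` with in-frame coding sequences keyed by species.

Stages
------
1. codon bias: ENC/GC3/length per gene and species from the sequences;
2. gene screen: per gene and response, the lambda-test routing between the
   Pearson and the phylogenetically corrected covariance test, then a
   Fisher exact test for enrichment of significant genes in the focal set;
3. coefficient comparison: bootstrap CIs and tests on per-gene Pearson r,
   and a t test on per-gene regression slopes;
4. contrast regressions: the multiple regressions on independent contrasts
   (omega and ENC responses).

Analyses restricted to the *D. melanogaster* subgroup skip phylogenetic
routing by design (Pearson only): with five taxa the likelihood surface is
too parameter-rich to make the lambda test meaningful.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codonstats, stats
from .matching import stable_seed
from .pgls import ScreenResult, pearson_test, route_correlation_test, screen_table
from .phylo import Phylogeny, parse_newick
from .synth import read_study

__all__ = [
    "PipelineError",
    "StudyConfig",
    "ScreenReport",
    "CoefficientComparison",
    "te_abundance_from_percent",
    "run_gene_screen",
    "run_coefficient_comparison",
    "run_full_study",
]

log = logging.getLogger("tephylo")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class StudyConfig:
    study_dir: str
    output_dir: str = "results/study_out"
    alpha: float = 0.05
    n_boot: int = 10000
    n_perm: int = 9999
    seed: int = 0
    model: str = "auto"               # GLS mean-structure policy
    responses: tuple = ("omega",)
    subgroup: tuple | None = None     # tip labels for the reduced panel
    exclude_ds_only: bool = False     # the dS-but-not-dN exclusion rule

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise PipelineError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        data["responses"] = tuple(data.get("responses", ("omega",)))
        if data.get("subgroup"):
            data["subgroup"] = tuple(data["subgroup"])
        return cls(**data)


@dataclass
class ScreenReport:
    results: dict                     # (set, response) -> list[ScreenResult]
    tables: dict                      # (set, response) -> DataFrame
    counts: dict                      # response -> (a, b, c, d)
    enrichment: dict                  # response -> Fisher two-tailed p


@dataclass
class CoefficientComparison:
    r: dict                           # set -> per-gene Pearson r
    beta: dict                        # set -> per-gene OLS slopes
    ci: dict                          # set -> BootstrapResult for mean r
    diff_p: float                     # P(mean r control <= mean r focal)
    t: float
    t_p: float
    summary: pd.DataFrame


def te_abundance_from_percent(percent_repeat: float, genome_size_mb: float) -> float:
    """Genomic TE abundance (Mb) as percent repeat content times assembled
    genome size."""
    if not 0.0 <= percent_repeat <= 100.0:
        raise PipelineError(
            f"percent repeat must lie in [0, 100], got {percent_repeat}"
        )
    if genome_size_mb <= 0.0:
        raise PipelineError("genome size must be positive")
    return percent_repeat / 100.0 * genome_size_mb


def _check_complete(panel: pd.DataFrame, tips, responses) -> None:
    for resp in responses:
        if resp not in panel.columns:
            raise PipelineError(f"response {resp!r} missing from trait table")
        for gene, sub in panel.groupby("gene"):
            sub = sub.set_index("species")
            for sp in tips:
                if sp not in sub.index or pd.isna(sub.loc[sp, resp]):
                    raise PipelineError(
                        f"missing value: gene {gene!r}, species {sp!r}, "
                        f"trait {resp!r}"
                    )


def run_gene_screen(
    panel: pd.DataFrame,
    te: pd.Series,
    tree: Phylogeny,
    responses: tuple = ("omega",),
    alpha: float = 0.05,
    model: str = "auto",
    exclude_ds_only: bool = False,
    bh_correct: bool = False,
) -> ScreenReport:
    """Per-gene correlation screen with lambda-test routing, one table per
    (gene set, response), plus the significant-gene enrichment test.

    ``bh_correct`` applies a Benjamini-Hochberg adjustment to the routed
    p-values across all genes within each response before significance is
    counted (off by default: the screens are reported uncorrected).
    """
    tips = tree.tip_labels
    _check_complete(panel, tips, responses)
    results: dict = {}
    sig: dict = {}
    for resp in responses:
        for gset, sub in panel.groupby("set"):
            out = []
            for gene, g in sub.groupby("gene"):
                g = g.set_index("species")
                Y = pd.DataFrame(
                    {"te": te.loc[tips], resp: g.loc[tips, resp]}
                )
                r = route_correlation_test(
                    Y, tree, alpha=alpha, model=model, gene=gene
                )
                log.info(
                    "screen gene=%s set=%s response=%s route=%s p=%.4g",
                    gene, gset, resp, r.route, r.final_p,
                )
                out.append(r)
                sig[(gene, resp)] = r.final_p < alpha
            results[(gset, resp)] = out
        if bh_correct:
            from statsmodels.stats.multitest import multipletests

            items = [
                (r.gene, r.final_p)
                for gset in panel["set"].unique()
                for r in results[(gset, resp)]
            ]
            reject = multipletests(
                [p for _, p in items], alpha=alpha, method="fdr_bh"
            )[0]
            for (gene, _), rej in zip(items, reject):
                sig[(gene, resp)] = bool(rej)
    counts: dict = {}
    enrichment: dict = {}
    gene_sets = {g: s for g, s in panel[["gene", "set"]].drop_duplicates().values}
    for resp in responses:
        pi = [g for g, s in gene_sets.items() if s == "piRNA"]
        ct = [g for g, s in gene_sets.items() if s == "control"]
        a = sum(sig[(g, resp)] for g in pi)
        c = sum(sig[(g, resp)] for g in ct)
        counts[resp] = (a, len(pi) - a, c, len(ct) - c)
        enrichment[resp] = stats.fisher_exact_2tail(*counts[resp])
    if exclude_ds_only and {"omega", "dn", "ds"} <= set(responses):
        # exclude genes whose signal is dS-driven (significant for dS but
        # not dN) and recompute the omega enrichment
        pi = [g for g, s in gene_sets.items() if s == "piRNA"]
        ct = [g for g, s in gene_sets.items() if s == "control"]
        drop = {
            g
            for g in gene_sets
            if sig[(g, "ds")] and not sig[(g, "dn")]
        }
        pi = [g for g in pi if g not in drop]
        ct = [g for g in ct if g not in drop]
        a = sum(sig[(g, "omega")] for g in pi)
        c = sum(sig[(g, "omega")] for g in ct)
        counts["omega_excluding_ds_only"] = (a, len(pi) - a, c, len(ct) - c)
        enrichment["omega_excluding_ds_only"] = stats.fisher_exact_2tail(
            a, len(pi) - a, c, len(ct) - c
        )
    tables = {key: screen_table(res) for key, res in results.items()}
    return ScreenReport(
        results=results, tables=tables, counts=counts, enrichment=enrichment
    )


def run_subgroup_screen(
    panel: pd.DataFrame,
    te: pd.Series,
    tree: Phylogeny,
    subgroup: tuple,
    response: str = "omega",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson-only per-gene screen on a pruned subgroup phylogeny (no
    lambda-test routing, by design)."""
    sub_tree = tree.prune(subgroup)
    tips = sub_tree.tip_labels
    rows = []
    for (gset, gene), g in panel.groupby(["set", "gene"]):
        g = g.set_index("species")
        pt = pearson_test(
            te.loc[tips].to_numpy(), g.loc[tips, response].to_numpy()
        )
        rows.append(
            {
                "Gene": gene,
                "set": gset,
                "r": pt.r,
                "beta": pt.beta,
                "R^2": pt.r**2,
                "p-value": pt.p,
                "significant": pt.p < alpha,
            }
        )
    return pd.DataFrame(rows)


def run_coefficient_comparison(
    panel: pd.DataFrame,
    te: pd.Series,
    tree: Phylogeny,
    response: str = "omega",
    species: tuple | None = None,
    n_boot: int = 10000,
    seed: int = 0,
) -> CoefficientComparison:
    """Distribution of per-gene correlation coefficients and slopes between
    the two gene sets: bootstrap CI per set, a one-sided bootstrap test that
    the control mean r exceeds the focal mean r, and a t test on slopes."""
    tips = list(species) if species is not None else tree.tip_labels
    r: dict = {"piRNA": [], "control": []}
    beta: dict = {"piRNA": [], "control": []}
    for (gset, gene), g in panel.groupby(["set", "gene"]):
        g = g.set_index("species")
        pt = pearson_test(
            te.loc[tips].to_numpy(), g.loc[tips, response].to_numpy()
        )
        r[gset].append(pt.r)
        beta[gset].append(pt.beta)
    ci = {
        s: stats.bootstrap_mean_ci(
            r[s], n_boot=n_boot, seed=stable_seed(seed, "ci", s)
        )
        for s in r
    }
    diff_p = stats.bootstrap_mean_diff_test(
        r["control"], r["piRNA"], n_boot=n_boot, seed=stable_seed(seed, "diff")
    )
    t, t_p = stats.slope_ttest(beta["control"], beta["piRNA"])
    summary = pd.DataFrame(
        [
            {
                "set": s,
                "mean_r": ci[s].estimate,
                "ci_low": ci[s].ci_low,
                "ci_high": ci[s].ci_high,
                "mean_beta": float(np.mean(beta[s])),
                "n_genes": len(r[s]),
            }
            for s in ("control", "piRNA")
        ]
    )
    return CoefficientComparison(
        r=r, beta=beta, ci=ci, diff_p=diff_p, t=t, t_p=t_p, summary=summary
    )


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_full_study(config: StudyConfig) -> dict:
    """Execute every stage on a study directory and write all tables, a
    provenance record, and a log under ``config.output_dir``.

    Returns a dict of the in-memory results keyed by stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = read_study(config.study_dir)
    tree, te, panel = study.tree, study.te, study.panel.copy()
    results: dict = {}

    # stage: codon bias -----------------------------------------------------
    seqdir = Path(config.study_dir) / "sequences"
    if seqdir.is_dir():
        cb = _stage("codon-bias")(codonstats.codon_bias_table)(seqdir)
        cb = cb.rename(columns={"length_aa": "length"})
        panel = panel.drop(
            columns=[c for c in ("enc", "gc3", "length") if c in panel.columns]
        ).merge(
            cb[["gene", "species", "enc", "gc3", "length"]],
            on=["gene", "species"],
            how="left",
        )
        cb.to_csv(outdir / "codon_bias.tsv", sep="\t", index=False)
        results["codon_bias"] = cb

    # stage: gene screen ----------------------------------------------------
    responses = tuple(r for r in config.responses if r in panel.columns)
    if not responses:
        raise PipelineError(
            f"stage 'gene-screen' failed: none of {config.responses} present"
        )
    screen = _stage("gene-screen")(run_gene_screen)(
        panel, te, tree,
        responses=responses, alpha=config.alpha, model=config.model,
        exclude_ds_only=config.exclude_ds_only,
    )
    for (gset, resp), tab in screen.tables.items():
        tab.to_csv(
            outdir / f"screen_{resp}_{gset}.tsv", sep="\t", index=False,
            na_rep="NA",
        )
    results["screen"] = screen

    # stage: coefficient comparison ----------------------------------------
    comp = _stage("coefficient-comparison")(run_coefficient_comparison)(
        panel, te, tree,
        response=responses[0], n_boot=config.n_boot,
        seed=stable_seed(config.seed, "compare"),
    )
    comp.summary.to_csv(outdir / "coefficient_comparison.tsv", sep="\t",
                        index=False)
    results["comparison"] = comp
    if config.subgroup:
        sub = _stage("subgroup-screen")(run_subgroup_screen)(
            panel, te, tree, config.subgroup,
            response=responses[0], alpha=config.alpha,
        )
        sub.to_csv(outdir / "subgroup_screen.tsv", sep="\t", index=False)
        comp_sub = _stage("coefficient-comparison")(run_coefficient_comparison)(
            panel, te, tree.prune(config.subgroup),
            response=responses[0], n_boot=config.n_boot,
            seed=stable_seed(config.seed, "compare-subgroup"),
        )
        comp_sub.summary.to_csv(
            outdir / "coefficient_comparison_subgroup.tsv", sep="\t",
            index=False,
        )
        results["comparison_subgroup"] = comp_sub

    # stage: contrast regressions --------------------------------------------
    regressions: dict = {}
    if "omega" in panel.columns:
        covs = tuple(c for c in ("gc3", "length") if c in panel.columns)
        reg = _stage("contrast-regression")(stats.contrast_regression)(
            panel, te, tree, response="omega", covariates=covs
        )
        stats.format_regression_table(reg.table).to_csv(
            outdir / "contrast_regression_omega.tsv", sep="\t", index=False
        )
        regressions["omega"] = reg
    if "enc" in panel.columns:
        covs = tuple(c for c in ("length", "omega") if c in panel.columns)
        reg = _stage("contrast-regression")(stats.contrast_regression)(
            panel, te, tree, response="enc", covariates=covs
        )
        stats.format_regression_table(reg.table).to_csv(
            outdir / "contrast_regression_enc.tsv", sep="\t", index=False
        )
        regressions["enc"] = reg
    results["regressions"] = regressions

    # provenance -------------------------------------------------------------
    cfg = asdict(config)
    provenance = {
        "config": cfg,
        "config_sha256": sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "enrichment": {k: v for k, v in screen.enrichment.items()},
        "counts": {k: list(v) for k, v in screen.counts.items()},
        "bootstrap_diff_p": comp.diff_p,
        "slope_t_p": comp.t_p,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n"
    )
    return results
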