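"""Validation of called eQTLs.

Three instruments, mirroring how a CSSL eQTL study is evaluated in the field:

* prediction of expression under a *new* environment, comparing the eQTL-based
  assignment of parental models against the plain background-genotype (BG)
  assignment, gene by gene;
* a marker-permutation test for mosaic-genome lines (BILs): the observed total
  prediction error under the eQTL model is compared with the distribution
  obtained by permuting the line's allele vector across markers (allele counts
  preserved), with an empirical p and an extreme-percentile threshold;
* Fisher's exact enrichment of annotation terms in a gene set, BH-adjusted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from .stats import bh_adjust

from .data_io import GenotypePanel, MeteoSeries
from .envmodel import design_for, _coef_vector
from .eqtl_scan import call_blocks, gene_assignment_p2


@dataclass
class PredictionSet:
    """eQTL-model and BG-model predictions for a set of genes on one sample set."""

    pred_eqtl: pd.DataFrame  # genes x samples
    pred_bg: pd.DataFrame
    assign_eqtl: pd.DataFrame  # genes x lines, 'P1'/'P2'
    assign_bg: pd.DataFrame
    differs: pd.Series  # gene -> True when the two assignments disagree somewhere


@dataclass
class ImprovementSummary:
    per_gene: pd.DataFrame  # error_eqtl, error_bg, differs, improved
    fraction_improved: float
    n_eligible: int


@dataclass
class PermutationTestResult:
    observed: float
    null: np.ndarray
    p: float
    threshold: float  # the extreme percentile of the null
    percentile: float
    total_p1: float  # reference: every gene predicted with the P1 model
    total_p2: float


def _line_assignment(panel: GenotypePanel, lines: pd.Index, calls: list) -> np.ndarray:
    """Parental assignment per line from a gene's selected calls: each block
    votes its consensus allele (ties to the representative marker); any
    non-background block vote switches the line to the donor parent's model.
    Returns a boolean 'use P2' per line."""
    A = panel.alleles.loc[lines].to_numpy() == "P2"
    bg_p2 = panel.background.loc[lines].to_numpy() == "P2"
    return gene_assignment_p2(A, call_blocks(calls, panel.marker_ids), bg_p2)


def predict_new_environment(
    models_p1: dict,
    models_p2: dict,
    calls_by_gene: dict,
    panel: GenotypePanel,
    meteo_new: MeteoSeries,
    samples_new: pd.DataFrame,
    genes=None,
) -> PredictionSet:
    """Predict each eQTL-influenced gene on new samples, under both the
    multi-eQTL assignment and the background assignment, from the SAME fitted
    parental models (no refitting).

    ``samples_new`` needs columns sampling_time, scaled_age, line_id.
    """
    if genes is None:
        genes = [g for g in calls_by_gene if calls_by_gene[g]]
    lines = pd.Index(pd.unique(samples_new["line_id"]))
    missing = lines.difference(panel.line_ids)
    if len(missing):
        raise KeyError(f"line {missing[0]!r} absent from the genotype panel")
    line_pos = {l: i for i, l in enumerate(lines)}
    sample_line_idx = np.array([line_pos[l] for l in samples_new["line_id"]])
    bg_p2 = (panel.background.loc[lines].to_numpy() == "P2")
    pe, pb, ae, ab, differs = {}, {}, {}, {}, {}
    cache: dict = {}
    for g in genes:
        calls = calls_by_gene.get(g, [])
        if not calls:
            warnings.warn(f"gene {g!r} has no eQTL call; falling back to the BG model")
        use_p2 = _line_assignment(panel, lines, calls) if calls else bg_p2
        yhat = {}
        for parent, model in (("P1", models_p1[g]), ("P2", models_p2[g])):
            key = (g, parent)
            if key not in cache:
                cache[key] = design_for(model, meteo_new, samples_new) @ _coef_vector(model)
            yhat[parent] = cache[key]
        eq = np.where(use_p2[sample_line_idx], yhat["P2"], yhat["P1"])
        bg = np.where(bg_p2[sample_line_idx], yhat["P2"], yhat["P1"])
        pe[g], pb[g] = eq, bg
        ae[g] = np.where(use_p2, "P2", "P1")
        ab[g] = np.where(bg_p2, "P2", "P1")
        differs[g] = bool((use_p2 != bg_p2).any())
    idx = samples_new.index
    return PredictionSet(
        pred_eqtl=pd.DataFrame(pe, index=idx).T,
        pred_bg=pd.DataFrame(pb, index=idx).T,
        assign_eqtl=pd.DataFrame(ae, index=lines).T,
        assign_bg=pd.DataFrame(ab, index=lines).T,
        differs=pd.Series(differs),
    )


def improvement_fraction(
    predictions: PredictionSet,
    observed: pd.DataFrame,
    weights: pd.DataFrame,
) -> ImprovementSummary:
    """Per-gene weighted squared prediction errors under both assignments;
    a gene counts as improved when the eQTL-model error is strictly smaller.
    The fraction is taken over genes whose assignments actually differ."""
    genes = predictions.pred_eqtl.index
    samples = predictions.pred_eqtl.columns
    Y = observed.loc[genes, samples].to_numpy(float)
    W = weights.loc[genes, samples].to_numpy(float)
    Ee = (W * (Y - predictions.pred_eqtl.to_numpy()) ** 2).sum(axis=1)
    Eb = (W * (Y - predictions.pred_bg.to_numpy()) ** 2).sum(axis=1)
    differs = predictions.differs.loc[genes].to_numpy(bool)
    per_gene = pd.DataFrame(
        {"error_eqtl": Ee, "error_bg": Eb, "differs": differs, "improved": Ee < Eb},
        index=genes,
    )
    if not differs.any():
        raise ValueError("no gene with an assignment differing from background")
    frac = float(per_gene.loc[differs, "improved"].mean())
    return ImprovementSummary(per_gene, frac, int(differs.sum()))


def bil_permutation_test(
    genes,
    models_p1: dict,
    models_p2: dict,
    calls_by_gene: dict,
    panel: GenotypePanel,
    bil_line: str,
    observed: pd.DataFrame,
    weights: pd.DataFrame,
    meteo: MeteoSeries,
    samples: pd.DataFrame,
    n_perm: int = 10_000,
    percentile: float = 0.001,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Total weighted prediction error for one BIL over the eQTL-influenced
    genes, against a null that permutes the BIL's allele vector across markers.

    p = (1 + #{null <= observed}) / (n_perm + 1); ``threshold`` is the
    ``percentile`` quantile of the null.  With all alleles identical the test
    is degenerate and returns p = 1.
    """
    sub = samples[samples["line_id"] == bil_line]
    if len(sub) == 0:
        raise ValueError(f"no samples for line {bil_line!r}")
    alleles = panel.alleles.loc[bil_line].to_numpy()
    genes = [g for g in genes if calls_by_gene.get(g)]
    # per-gene error totals under each pure parental model on the BIL samples
    E1 = np.empty(len(genes))
    E2 = np.empty(len(genes))
    blocks = []
    for i, g in enumerate(genes):
        y = observed.loc[g, sub.index].to_numpy(float)
        w = weights.loc[g, sub.index].to_numpy(float)
        for parent, models, out in (("P1", models_p1, E1), ("P2", models_p2, E2)):
            yhat = design_for(models[g], meteo, sub) @ _coef_vector(models[g])
            out[i] = float(np.sum(w * (y - yhat) ** 2))
        blocks.append(call_blocks(calls_by_gene[g], panel.marker_ids))

    bil_bg_p2 = panel.background[bil_line] == "P2"

    def total_error(vecs_is_p2: np.ndarray) -> np.ndarray:
        """Total error per allele vector (rows of ``vecs_is_p2``)."""
        tot = np.zeros(len(vecs_is_p2))
        bg = np.full(len(vecs_is_p2), bil_bg_p2)
        for i in range(len(genes)):
            use_p2 = gene_assignment_p2(vecs_is_p2, blocks[i], bg)
            tot += np.where(use_p2, E2[i], E1[i])
        return tot

    is_p2 = alleles == "P2"
    obs = float(total_error(is_p2[None, :])[0])
    M = len(alleles)
    if is_p2.all() or (~is_p2).all():
        warnings.warn(f"line {bil_line!r} carries one allele everywhere; test degenerate")
        null = np.full(max(n_perm, 1), obs)
        return PermutationTestResult(obs, null, 1.0, obs, percentile, float(E1.sum()), float(E2.sum()))
    if exhaustive:
        if M > 7:
            raise ValueError("exhaustive enumeration supported only for <= 7 markers")
        null = total_error(np.stack([is_p2[list(pm)] for pm in itertools.permutations(range(M))]))
    else:
        rng = np.random.default_rng(seed)
        null = total_error(np.stack([is_p2[rng.permutation(M)] for _ in range(n_perm)]))
    p = (1.0 + np.sum(null <= obs + 1e-12)) / (len(null) + 1.0)
    thr = float(np.quantile(null, percentile))
    return PermutationTestResult(obs, null, float(p), thr, percentile, float(E1.sum()), float(E2.sum()))


def enrichment_test(gene_set, universe, annotation: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Fisher exact test per annotation term, BH-adjusted.

    ``annotation`` has columns gene_id, term; only universe genes count.
    Returns a per-term table sorted by adjusted p.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set or not universe:
        raise ValueError("gene_set and universe must be non-empty")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    ann = annotation[annotation["gene_id"].isin(universe)]
    n_set = len(gene_set)
    n_rest = len(universe) - n_set
    rows = []
    for term, grp in ann.groupby("term"):
        members = set(grp["gene_id"])
        a = len(members & gene_set)
        b = n_set - a
        c = len(members) - a
        d = n_rest - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        odds = (a * d) / (b * c) if b * c != 0 else (1.0 if a * d == 0 else np.inf)
        rows.append({"term": term, "n_set": a, "n_term": len(members), "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows, columns=["term", "n_set", "n_term", "odds_ratio", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
        out = out.sort_values(["p_adj", "term"]).reset_index(drop=True)
    else:
        out["p_adj"] = []
        out["significant"] = []
    return out
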