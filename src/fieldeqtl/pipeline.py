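"""End-to-end orchestration: preprocess -> parental model fits -> polymorphism
test -> marker scan -> calls.  The same entry points serve the command-line
interface, the test-suite and the acceptance script."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import envmodel, eqtl_scan, preprocess
from .data_io import GenotypePanel, MeteoSeries
from .synthetic import SimBundle


@dataclass
class StudyResult:
    expr: preprocess.ExpressionData
    grid: list
    ctx_all: envmodel.FitContext
    models_p1: dict
    models_p2: dict
    polymorphism: pd.DataFrame
    profiles: dict
    perms: dict
    calls: list
    train_samples: pd.DataFrame

    @property
    def calls_by_gene(self) -> dict:
        by = {}
        for c in self.calls:
            by.setdefault(c.gene_id, []).append(c)
        return by

    @property
    def called_genes(self) -> list:
        return sorted(self.calls_by_gene)


def fit_parental_models(
    expr: preprocess.ExpressionData,
    panel: GenotypePanel,
    meteo: MeteoSeries,
    exclude_lines=(),
    grid=None,
):
    """Fit both parents' per-gene models on background-concordant samples
    (each parent with its own background's lines), excluding held-out lines
    such as BILs."""
    samples = expr.samples_frame()
    train = samples[~samples["line_id"].isin(exclude_lines)]
    grid = grid if grid is not None else envmodel.default_grid(meteo)
    models = {}
    for parent in ("P1", "P2"):
        bg_lines = panel.background.index[panel.background == parent]
        sub = train[train["line_id"].isin(bg_lines)]
        ctx = envmodel.FitContext(meteo, sub, grid)
        Y = expr.log2rpm[sub.index]
        W = expr.weights[sub.index]
        models[parent] = envmodel.fit_gene_models(Y, W, ctx, parent)
    ctx_all = envmodel.FitContext(meteo, train, grid)
    return models["P1"], models["P2"], ctx_all, grid, train


def run_study(
    bundle: SimBundle,
    n_perm_poly: int = 200,
    n_perm_scan: int = 200,
    seed: int = 0,
    scan_genes=None,
    q_poly: float = 0.05,
    q_scan: float = 0.05,
    grid=None,
) -> StudyResult:
    """Full analysis of one (simulated or file-backed) study bundle.

    ``scan_genes``: override the polymorphism filter with an explicit gene
    list — e.g. force every gene through the scan on a null dataset when
    calibrating the false-discovery rate.
    """
    expr = preprocess.preprocess_counts(bundle.counts, bundle.meta, bundle.panel.heading_days)
    models_p1, models_p2, ctx_all, grid, train = fit_parental_models(
        expr, bundle.panel, bundle.meteo, exclude_lines=bundle.bil_lines, grid=grid
    )
    line_bg = bundle.panel.background.drop(list(bundle.bil_lines))
    Y = expr.log2rpm[train.index]
    W = expr.weights[train.index]
    poly = envmodel.polymorphism_scan(
        Y, W, ctx_all, train["line_id"], line_bg,
        models_p1, models_p2, n_perm=n_perm_poly, seed=seed, q_threshold=q_poly,
    )
    if scan_genes is None:
        scan_genes = list(poly.index[poly["polymorphic"]])
    else:
        scan_genes = [g for g in scan_genes if g in Y.index]
    profiles, perms = eqtl_scan.scan_study(
        Y, W, models_p1, models_p2, bundle.panel, ctx_all, train["line_id"],
        genes=scan_genes, n_perm=n_perm_scan, seed=seed + 1,
    )
    calls = eqtl_scan.call_eqtls(
        profiles, perms, bundle.panel, bundle.gene_positions, q_threshold=q_scan
    )
    return StudyResult(
        expr=expr, grid=grid, ctx_all=ctx_all,
        models_p1=models_p1, models_p2=models_p2,
        polymorphism=poly, profiles=profiles, perms=perms, calls=calls,
        train_samples=train,
    )


def validation_expression(
    bundle_valid: SimBundle,
    train_expr: preprocess.ExpressionData,
) -> preprocess.ExpressionData:
    """Preprocess a validation-season bundle on the training gene list."""
    return preprocess.preprocess_counts(
        bundle_valid.counts, bundle_valid.meta, bundle_valid.panel.heading_days,
        genes=train_expr.kept_genes,
    )
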