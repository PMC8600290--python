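"""Per-gene, per-parent models of expression dynamics under field conditions.

Each gene's log2rpm trajectory is modelled as a linear combination of

* a circadian clock harmonic ``a*cos(2*pi*h/24) + b*sin(2*pi*h/24)``,
* a linear term in *scaled age* (days after sowing / days to heading), and
* one gated-window environmental feature ``E`` — the mean of
  ``max(x(u) - theta, 0)`` over the ``w`` hours preceding sampling, where
  ``x`` is minute-resolution air temperature or global solar radiation.

The term subset, the environmental variable, the window ``w`` and the gate
``theta`` are chosen jointly by AIC over a fixed grid, fitting weighted least
squares at every grid point.  Parental polymorphism in the fitted dynamics is
tested by a shared-vs-separate weighted RSS reduction with a line-level
permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from .stats import bh_adjust

from .data_io import MeteoSeries

TERMS = ("clock", "age", "env")
DEFAULT_WINDOWS_H = (1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0)
THRESHOLD_QUANTILES = (0.0, 0.25, 0.5, 0.75)
RSS_FLOOR = 1e-10  # keeps AIC finite on saturated (noiseless) fits
# An env candidate is chosen by searching three grid dimensions (variable,
# window, gate); those searched hyperparameters count toward its complexity,
# otherwise the best of ~200 correlated grid fits beats the 2-per-parameter
# AIC penalty and a spurious env term is admitted for most null genes.
ENV_SEARCH_PARAMS = 3
_BASES = (frozenset(), frozenset({"clock"}), frozenset({"age"}), frozenset({"clock", "age"}))


@dataclass(frozen=True)
class EnvFeatureSpec:
    """One gated-window weather feature: variable, window length, gate threshold."""

    variable: str  # 'temperature' | 'radiation'
    window_hours: float
    gate_threshold: float

    def __post_init__(self):
        if self.window_hours <= 0:
            raise ValueError("window_hours must be positive")
        if self.variable not in ("temperature", "radiation"):
            raise ValueError(f"unknown variable {self.variable!r}")


@dataclass
class GeneModel:
    """AIC-selected fit for one gene in one parental background."""

    gene_id: str
    parent: str
    included_terms: frozenset
    mu: float
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    env_spec: Optional[EnvFeatureSpec] = None
    rss_w: float = np.nan
    n: int = 0
    k: int = 1
    aic: float = np.nan


@dataclass
class PolymorphismResult:
    gene_id: str
    statistic: float
    p: float
    q: float
    polymorphic: bool
    terms_p1: frozenset
    terms_p2: frozenset


def default_grid(
    meteo: MeteoSeries,
    windows: Sequence[float] = DEFAULT_WINDOWS_H,
    quantiles: Sequence[float] = THRESHOLD_QUANTILES,
) -> list[EnvFeatureSpec]:
    """Grid of env features: gates at season-wide quantiles of each variable."""
    specs = []
    for var in ("temperature", "radiation"):
        x = meteo.frame[var].to_numpy(float)
        thetas = sorted({round(float(np.quantile(x, q)), 6) for q in quantiles})
        for theta in thetas:
            for w in windows:
                specs.append(EnvFeatureSpec(var, float(w), theta))
    return specs


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def clock_basis(sampling_time):
    """(cos, sin) of the 24 h harmonic at the fractional hour of day."""
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(sampling_time, dtype="datetime64[ns]")))
    h = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    ang = 2.0 * np.pi * np.asarray(h) / 24.0
    cos, sin = np.cos(ang), np.sin(ang)
    if np.ndim(sampling_time) == 0:
        return float(cos[0]), float(sin[0])
    return cos, sin


def _minute_axis(meteo: MeteoSeries):
    idx = meteo.frame.index
    if len(idx) < 2 or (idx[1] - idx[0]) != pd.Timedelta(minutes=1):
        raise ValueError("weather series must be at 1-minute resolution; interpolate first")
    return idx[0], len(idx)


def _minute_offsets(meteo: MeteoSeries, times) -> np.ndarray:
    t0, _ = _minute_axis(meteo)
    off = (pd.DatetimeIndex(times) - t0) / pd.Timedelta(minutes=1)
    off = np.asarray(off, float)
    if not np.allclose(off, np.round(off)):
        raise ValueError("sampling times must align to the weather minute grid")
    return np.round(off).astype(np.int64)


def env_feature(meteo: MeteoSeries, sampling_time, spec: EnvFeatureSpec) -> float:
    """Mean of max(x - theta, 0) over the window [t - w, t)."""
    return float(env_features_matrix(meteo, [pd.Timestamp(sampling_time)], [spec])[0, 0])


def env_features_matrix(meteo: MeteoSeries, times, specs) -> np.ndarray:
    """samples x specs matrix of gated-window features (vectorised via cumsums)."""
    t0, n = _minute_axis(meteo)
    idx = _minute_offsets(meteo, times)
    out = np.empty((len(idx), len(specs)), float)
    csums: dict[tuple, np.ndarray] = {}
    for j, spec in enumerate(specs):
        wm = int(round(spec.window_hours * 60))
        lo, hi = idx - wm, idx
        if lo.size and lo.min() < 0:
            t_bad = t0 + pd.Timedelta(minutes=int(idx[lo.argmin()]))
            raise ValueError(
                f"insufficient weather history: sample at {t_bad} needs "
                f"{spec.window_hours} h before the series start {t0}"
            )
        if hi.size and hi.max() > n:
            raise ValueError("sampling time beyond the end of the weather series")
        key = (spec.variable, spec.gate_threshold)
        if key not in csums:
            x = meteo.frame[spec.variable].to_numpy(float)
            gated = np.maximum(x - spec.gate_threshold, 0.0)
            csums[key] = np.concatenate([[0.0], np.cumsum(gated)])
        cs = csums[key]
        out[:, j] = (cs[hi] - cs[lo]) / wm
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class FitContext:
    """Precomputed design columns for a fixed sample set, weather series and grid.

    ``samples`` is a DataFrame indexed by sample id with columns
    ``sampling_time`` and ``scaled_age``.  Column layout of the design matrix:
    0 intercept, 1 cos, 2 sin, 3 scaled age, then one column per grid spec.
    """

    def __init__(self, meteo: MeteoSeries, samples: pd.DataFrame, grid=None):
        self.meteo = meteo
        self.samples = samples
        self.grid = list(grid) if grid is not None else default_grid(meteo)
        n = len(samples)
        cos, sin = clock_basis(samples["sampling_time"].to_numpy())
        X = np.empty((n, 4 + len(self.grid)), float)
        X[:, 0] = 1.0
        X[:, 1] = cos
        X[:, 2] = sin
        X[:, 3] = samples["scaled_age"].to_numpy(float)
        if self.grid:
            X[:, 4:] = env_features_matrix(meteo, samples["sampling_time"].to_numpy(), self.grid)
        self.X = X
        self.spec_col = {spec: 4 + j for j, spec in enumerate(self.grid)}
        self._candidates = _candidate_table(len(self.grid))

    @property
    def n(self) -> int:
        return len(self.samples)

    def subset(self, mask) -> "FitContext":
        ctx = object.__new__(FitContext)
        ctx.meteo = self.meteo
        ctx.samples = self.samples.loc[mask]
        ctx.grid = self.grid
        ctx.X = self.X[np.asarray(mask)] if np.asarray(mask).dtype == bool else self.X[mask]
        ctx.spec_col = self.spec_col
        ctx._candidates = self._candidates
        return ctx


def _candidate_table(n_env: int):
    """Deterministic candidate sequence: env-free subsets first, then env grids."""
    cands = []
    for base in _BASES:
        cols = [0] + ([1, 2] if "clock" in base else []) + ([3] if "age" in base else [])
        cands.append((base, cols, None))
    for base in _BASES:
        cols = [0] + ([1, 2] if "clock" in base else []) + ([3] if "age" in base else [])
        for j in range(n_env):
            cands.append((base | {"env"}, cols + [4 + j], j))
    return cands


def model_columns(model: GeneModel, ctx: FitContext) -> list[int]:
    cols = [0]
    if "clock" in model.included_terms:
        cols += [1, 2]
    if "age" in model.included_terms:
        cols.append(3)
    if "env" in model.included_terms:
        cols.append(ctx.spec_col[model.env_spec])
    return cols


def _solve_psd(G, b):
    try:
        beta = np.linalg.solve(G, b)
        if np.all(np.isfinite(beta)):
            return beta
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv(G) @ b


def _aic(rss_w: float, n: int, k: int) -> float:
    return n * np.log(max(rss_w, RSS_FLOOR) / n) + 2 * k


def fit_gene_model(
    y,
    w,
    ctx: FitContext,
    gene_id: str = "",
    parent: str = "P1",
) -> GeneModel:
    """Weighted least squares over every term subset x env grid point; pick min AIC."""
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    n = ctx.n
    if len(y) != n or len(w) != n:
        raise ValueError("y/w length does not match the fit context")
    if n < 10:
        raise ValueError("need at least 10 samples to fit a gene model")
    if (w <= 0).any() or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    X = ctx.X
    G = X.T @ (X * w[:, None])
    b = X.T @ (w * y)
    yy = float(w @ (y * y))
    best = None
    dropped = False
    for terms, cols, _j in ctx._candidates:
        Gs = G[np.ix_(cols, cols)]
        eig = np.linalg.eigvalsh(Gs)
        if eig[-1] <= 0 or eig[0] <= eig[-1] * 1e-12:
            dropped = True
            continue
        beta = _solve_psd(Gs, b[cols])
        rss = max(yy - float(b[cols] @ beta), 0.0)
        k = len(cols) + (ENV_SEARCH_PARAMS if "env" in terms else 0)
        aic = _aic(rss, n, k)
        if best is None or aic < best[0] - 1e-12:
            best = (aic, terms, cols, beta, rss, k)
    if best is None:
        raise ValueError("design singular for every candidate model")
    if dropped:
        warnings.warn("singular design for some candidates; offending terms dropped")
    aic, terms, cols, beta, rss, k = best
    return _pack_model(gene_id, parent, terms, cols, beta, rss, n, k, aic, ctx)


def _pack_model(gene_id, parent, terms, cols, beta, rss, n, k, aic, ctx) -> GeneModel:
    coef = dict(zip(cols, beta))
    spec = None
    d = 0.0
    for c in cols:
        if c >= 4:
            spec = ctx.grid[c - 4]
            d = float(coef[c])
    return GeneModel(
        gene_id=gene_id,
        parent=parent,
        included_terms=frozenset(terms),
        mu=float(coef.get(0, 0.0)),
        a=float(coef.get(1, 0.0)),
        b=float(coef.get(2, 0.0)),
        c=float(coef.get(3, 0.0)),
        d=d,
        env_spec=spec,
        rss_w=float(rss),
        n=int(n),
        k=int(k),
        aic=float(aic),
    )


def fit_gene_models(Y: pd.DataFrame, W: pd.DataFrame, ctx: FitContext, parent: str) -> dict:
    """Fit every row of ``Y`` (genes x samples).  Fast path when each gene's
    weight vector is constant across samples (gene-level precision weights):
    coefficients then coincide with the unweighted fit and the Gram matrix is
    shared across genes."""
    Yv = Y.to_numpy(float)
    Wv = W.to_numpy(float)
    if not np.allclose(Wv, Wv[:, [0]]):
        return {
            g: fit_gene_model(Yv[i], Wv[i], ctx, gene_id=g, parent=parent)
            for i, g in enumerate(Y.index)
        }
    wg = Wv[:, 0]
    X = ctx.X
    n, _p = X.shape
    G0 = X.T @ X
    B = Yv @ X  # genes x p
    yy = np.einsum("gs,gs->g", Yv, Yv)
    n_genes = len(Y.index)
    n_cand = len(ctx._candidates)
    rss_u = np.full((n_genes, n_cand), np.inf)
    ks = np.zeros(n_cand, dtype=int)
    betas: list = [None] * n_cand
    for ci, (terms, cols, _j) in enumerate(ctx._candidates):
        ks[ci] = len(cols) + (ENV_SEARCH_PARAMS if "env" in terms else 0)
        Gs = G0[np.ix_(cols, cols)]
        eig = np.linalg.eigvalsh(Gs)
        if eig[-1] <= 0 or eig[0] <= eig[-1] * 1e-12:
            continue
        inv = np.linalg.inv(Gs)
        Bsub = B[:, cols]
        beta = Bsub @ inv.T  # genes x k
        rss_u[:, ci] = np.maximum(yy - np.einsum("gk,gk->g", Bsub, beta), 0.0)
        betas[ci] = beta
    rss_w = rss_u * wg[:, None]
    aic = n * np.log(np.maximum(rss_w, RSS_FLOOR) / n) + 2 * ks[None, :]
    aic[~np.isfinite(aic)] = np.inf
    pick = np.argmin(aic, axis=1)
    models = {}
    for i, g in enumerate(Y.index):
        ci = int(pick[i])
        terms, cols, _j = ctx._candidates[ci]
        models[g] = _pack_model(
            g, parent, terms, cols, betas[ci][i], float(rss_w[i, ci]), n, int(ks[ci]),
            float(aic[i, ci]), ctx,
        )
    return models


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def design_for(model: GeneModel, meteo: MeteoSeries, samples: pd.DataFrame) -> np.ndarray:
    """n x k design for a fitted model on arbitrary samples (order: mu,a,b,c,d)."""
    n = len(samples)
    cols = [np.ones(n)]
    if "clock" in model.included_terms:
        cos, sin = clock_basis(samples["sampling_time"].to_numpy())
        cols += [cos, sin]
    if "age" in model.included_terms:
        cols.append(samples["scaled_age"].to_numpy(float))
    if "env" in model.included_terms:
        cols.append(env_features_matrix(meteo, samples["sampling_time"].to_numpy(), [model.env_spec])[:, 0])
    return np.column_stack(cols)


def _coef_vector(model: GeneModel) -> np.ndarray:
    coef = [model.mu]
    if "clock" in model.included_terms:
        coef += [model.a, model.b]
    if "age" in model.included_terms:
        coef.append(model.c)
    if "env" in model.included_terms:
        coef.append(model.d)
    return np.asarray(coef, float)


def predict(model: GeneModel, meteo: MeteoSeries, samples: pd.DataFrame) -> pd.Series:
    """Predicted log2rpm: mu + a*cos + b*sin + c*scaled_age + d*E, absent terms omitted."""
    yhat = design_for(model, meteo, samples) @ _coef_vector(model)
    return pd.Series(yhat, index=samples.index)


def weighted_rss(y, yhat, w) -> float:
    y, yhat, w = (np.asarray(v, float) for v in (y, yhat, w))
    return float(np.sum(w * (y - yhat) ** 2))


# ---------------------------------------------------------------------------
# polymorphism test
# ---------------------------------------------------------------------------


def _union_model_cols(m1: GeneModel, m2: GeneModel, ctx: FitContext) -> list[int]:
    """Columns of the shared model: union of parental term sets; if both carry an
    env term, the lower-AIC parent's spec wins."""
    cols = [0]
    if "clock" in m1.included_terms or "clock" in m2.included_terms:
        cols += [1, 2]
    if "age" in m1.included_terms or "age" in m2.included_terms:
        cols.append(3)
    spec = None
    if m1.env_spec is not None and m2.env_spec is not None:
        spec = m1.env_spec if m1.aic <= m2.aic else m2.env_spec
    elif m1.env_spec is not None:
        spec = m1.env_spec
    elif m2.env_spec is not None:
        spec = m2.env_spec
    if spec is not None:
        cols.append(ctx.spec_col[spec])
    return cols


def _per_line_stats(X, Yv, line_codes, n_lines):
    p = X.shape[1]
    n_genes = Yv.shape[0]
    Gl = np.zeros((n_lines, p, p))
    Bl = np.zeros((n_lines, p, n_genes))
    yyl = np.zeros((n_lines, n_genes))
    for l in range(n_lines):
        m = line_codes == l
        Xl = X[m]
        Gl[l] = Xl.T @ Xl
        Bl[l] = Xl.T @ Yv[:, m].T
        yyl[l] = np.einsum("gs,gs->g", Yv[:, m], Yv[:, m])
    return Gl, Bl, yyl


def _group_rss(Gl, Bl, yyl, mask, cols, g):
    """RSS of a fixed-structure fit on the lines selected by ``mask`` (batched over
    permutations when mask is 2-D)."""
    sub = Gl[:, cols][:, :, cols]  # (lines, k, k)
    bsub = Bl[:, cols, g]
    if mask.ndim == 1:
        G = np.einsum("l,lij->ij", mask, sub)
        b = mask @ bsub
        yy = float(mask @ yyl[:, g])
        beta = _solve_psd(G, b)
        return max(yy - float(b @ beta), 0.0)
    G = np.einsum("pl,lij->pij", mask, sub)
    b = mask @ bsub
    yy = mask @ yyl[:, g]
    try:
        beta = np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.einsum("pij,pj->pi", np.linalg.pinv(G), b)
    return np.maximum(yy - np.einsum("pk,pk->p", b, beta), 0.0)


def polymorphism_scan(
    Y: pd.DataFrame,
    W: pd.DataFrame,
    ctx: FitContext,
    sample_lines: pd.Series,
    line_background: pd.Series,
    models_p1: dict,
    models_p2: dict,
    n_perm: int = 500,
    seed: int = 0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Shared-vs-separate RSS reduction for every gene, with a line-level
    permutation null and BH adjustment across genes.

    Both the shared fit (all samples) and the two separate per-background fits
    use one fixed column set — the union of the parents' AIC-selected terms,
    with the lower-AIC parent's env feature — so the statistic isolates
    between-background heterogeneity.  Refitting each group with its own
    AIC-selected structure, or reusing fixed fitted coefficients, both leak
    the observed grouping into the statistic and push null p-values toward
    zero.  The per-gene weight must be constant across samples (gene-level
    precision weights); the statistic is reported on the weighted scale.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    genes = list(Y.index)
    Yv = Y.to_numpy(float)
    Wv = W.to_numpy(float)
    if not np.allclose(Wv, Wv[:, [0]]):
        raise ValueError("polymorphism_scan expects gene-level (constant) weights")
    wg = Wv[:, 0]
    lines = pd.Index(line_background.index)
    line_codes = lines.get_indexer(sample_lines.to_numpy())
    if (line_codes < 0).any():
        raise ValueError("sample assigned to a line absent from line_background")
    L = len(lines)
    X = ctx.X
    Gl, Bl, yyl = _per_line_stats(X, Yv, line_codes, L)
    G0 = Gl.sum(axis=0)
    bg_is_p1 = (line_background.to_numpy() == "P1").astype(float)
    perm_idx = np.stack([rng.permutation(L) for _ in range(n_perm)])
    mask_p1 = bg_is_p1[perm_idx]  # n_perm x L
    rows = []
    for g, gene in enumerate(genes):
        m1, m2 = models_p1[gene], models_p2[gene]
        cu = _union_model_cols(m1, m2, ctx)
        # shared fit on all samples; separate fits reuse the SAME union
        # structure per group, so the statistic measures group heterogeneity
        # rather than per-group structure selection
        bu = Bl[:, cu, g].sum(axis=0)
        Gu = G0[np.ix_(cu, cu)]
        beta = _solve_psd(Gu, bu)
        rss_shared = max(float(yyl[:, g].sum()) - float(bu @ beta), 0.0)
        rss1 = _group_rss(Gl, Bl, yyl, bg_is_p1, cu, g)
        rss2 = _group_rss(Gl, Bl, yyl, 1.0 - bg_is_p1, cu, g)
        T = (rss_shared - (rss1 + rss2)) * wg[g]
        rss1n = _group_rss(Gl, Bl, yyl, mask_p1, cu, g)
        rss2n = _group_rss(Gl, Bl, yyl, 1.0 - mask_p1, cu, g)
        T_null = (rss_shared - (rss1n + rss2n)) * wg[g]
        p = (1.0 + np.sum(T_null >= T - 1e-12)) / (n_perm + 1.0)
        rows.append((gene, T, p, m1.included_terms, m2.included_terms))
    out = pd.DataFrame(
        rows, columns=["gene", "statistic", "p", "terms_p1", "terms_p2"]
    ).set_index("gene")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["polymorphic"] = out["q"] < q_threshold
    for parent, col in (("p1", "terms_p1"), ("p2", "terms_p2")):
        for term in ("clock", "age", "env"):
            out[f"{term}_{parent}"] = [term in t for t in out[col]]
    return out


def polymorphism_test(
    gene_id: str,
    model_p1: GeneModel,
    model_p2: GeneModel,
    y,
    w,
    ctx: FitContext,
    sample_lines: pd.Series,
    line_background: pd.Series,
    n_perm: int = 500,
    seed: int = 0,
) -> PolymorphismResult:
    """Single-gene wrapper around :func:`polymorphism_scan` (q equals p when the
    scan covers one gene)."""
    Y = pd.DataFrame([np.asarray(y, float)], index=[gene_id])
    W = pd.DataFrame([np.asarray(w, float)], index=[gene_id])
    df = polymorphism_scan(
        Y, W, ctx, sample_lines, line_background,
        {gene_id: model_p1}, {gene_id: model_p2}, n_perm=n_perm, seed=seed,
    )
    r = df.loc[gene_id]
    return PolymorphismResult(
        gene_id=gene_id,
        statistic=float(r["statistic"]),
        p=float(r["p"]),
        q=float(r["q"]),
        polymorphic=bool(r["polymorphic"]),
        terms_p1=model_p1.included_terms,
        terms_p2=model_p2.included_terms,
    )
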