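"""Sample/gene quality filters, log2rpm normalisation, gene-level precision
weights, scaled age, minute-resolution weather interpolation, dark periods and
the between-sample Pearson correlation matrix."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CountMatrix, MeteoSeries, SampleMeta

MIN_TOTAL_READS = 100_000
MAX_DETECT_FRAC = 0.20
WEIGHT_EPS = 1e-6
DARK_RADIATION = 0.3  # kJ m^-2 min^-1


@dataclass
class ExpressionData:
    """Analysis-ready expression: log2rpm, precision weights, metadata, scaled age."""

    log2rpm: pd.DataFrame  # genes x samples
    weights: pd.DataFrame  # genes x samples, positive
    meta: SampleMeta
    scaled_age: pd.Series  # sample -> float

    def __post_init__(self):
        if self.log2rpm.shape != self.weights.shape:
            raise ValueError("log2rpm and weights must share a shape")
        if not np.all(np.isfinite(self.log2rpm.to_numpy())):
            raise ValueError("log2rpm must be finite")
        w = self.weights.to_numpy()
        if not (np.all(np.isfinite(w)) and (w > 0).all()):
            raise ValueError("weights must be positive and finite")

    @property
    def kept_genes(self) -> pd.Index:
        return self.log2rpm.index

    @property
    def kept_samples(self) -> pd.Index:
        return self.log2rpm.columns

    def samples_frame(self) -> pd.DataFrame:
        """Per-sample table (sampling_time, scaled_age, line_id) for model fitting."""
        t = self.meta.table.loc[self.kept_samples]
        return pd.DataFrame(
            {
                "sampling_time": t["sampling_time"],
                "scaled_age": self.scaled_age.loc[self.kept_samples],
                "line_id": t["line_id"],
            }
        )


@dataclass
class CorrelationMatrix:
    sample_ids: pd.Index
    rho: pd.DataFrame
    undefined: tuple = ()  # samples with zero variance


def filter_samples(counts: CountMatrix, min_total: int = MIN_TOTAL_READS) -> pd.Index:
    """Keep samples whose total read count is strictly greater than ``min_total``."""
    totals = counts.counts.sum(axis=0)
    return counts.sample_ids[totals > min_total]


def filter_genes(counts: CountMatrix, max_detect_frac: float = MAX_DETECT_FRAC) -> pd.Index:
    """Drop genes detected (count > 0) in at most ``max_detect_frac`` of samples."""
    n = counts.counts.shape[1]
    if n == 0:
        return counts.gene_ids[:0]
    detect = (counts.counts.to_numpy() > 0).sum(axis=1) / n
    return counts.gene_ids[detect > max_detect_frac]


def to_log2rpm(counts: CountMatrix) -> pd.DataFrame:
    """log2(rpm + 1), rpm normalised to the totals over the genes present."""
    totals = counts.counts.sum(axis=0).to_numpy(float)
    if (totals == 0).any():
        sid = counts.sample_ids[np.nonzero(totals == 0)[0][0]]
        raise ValueError(f"sample {sid!r} has zero total count")
    rpm = counts.counts.to_numpy(float) * 1e6 / totals[None, :]
    return pd.DataFrame(np.log2(rpm + 1.0), index=counts.gene_ids, columns=counts.sample_ids)


def precision_weights(log2rpm: pd.DataFrame, n_bins: int = 20, eps: float = WEIGHT_EPS) -> pd.DataFrame:
    """Gene-level precision weights from a mean-variance trend.

    Genes are binned by the rank of their mean log2rpm; the trend v(m) is the
    median within-bin mean squared residual (about the gene mean); the weight
    of every observation of gene g is 1 / max(v(m_g), eps).
    """
    Y = log2rpm.to_numpy(float)
    n_genes, n_samples = Y.shape
    if n_genes < 10:
        warnings.warn("fewer than 10 genes; falling back to uniform weights")
        w = np.ones_like(Y)
        return pd.DataFrame(w, index=log2rpm.index, columns=log2rpm.columns)
    means = Y.mean(axis=1)
    resid2 = ((Y - means[:, None]) ** 2).mean(axis=1)
    order = np.argsort(means, kind="stable")
    bins = np.array_split(order, min(n_bins, max(2, n_genes // 5)))
    v = np.empty(n_genes)
    for b in bins:
        v[b] = np.median(resid2[b])
    w_gene = 1.0 / np.maximum(v, eps)
    W = np.repeat(w_gene[:, None], n_samples, axis=1)
    return pd.DataFrame(W, index=log2rpm.index, columns=log2rpm.columns)


def scaled_age(meta: SampleMeta, heading_days: pd.Series) -> pd.Series:
    """(fractional days since sowing) / heading_days for the sample's (line, set)."""
    t = meta.table
    keys = list(zip(t["line_id"], t["transplant_set"]))
    missing = [k for k in keys if k not in heading_days.index]
    if missing:
        raise ValueError(f"no heading day for (line, set) {missing[0]}")
    hd = heading_days.loc[keys].to_numpy(float)
    if (hd <= 0).any():
        raise ValueError("heading_days must be positive")
    days = ((t["sampling_time"] - t["sowing_date"]) / pd.Timedelta(days=1)).to_numpy(float)
    return pd.Series(days / hd, index=t.index)


def interpolate_meteo(meteo: MeteoSeries) -> MeteoSeries:
    """Linear interpolation of a coarser series onto a 1-minute grid; original
    points are preserved exactly."""
    f = meteo.frame
    idx = f.index
    grid = pd.date_range(idx[0], idx[-1], freq="1min")
    x = (idx - idx[0]) / pd.Timedelta(minutes=1)
    xq = (grid - idx[0]) / pd.Timedelta(minutes=1)
    out = {
        col: np.interp(np.asarray(xq, float), np.asarray(x, float), f[col].to_numpy(float))
        for col in ("temperature", "radiation")
    }
    frame = pd.DataFrame(out, index=grid)
    frame.loc[idx] = f[["temperature", "radiation"]]
    return MeteoSeries(frame)


def dark_periods(meteo: MeteoSeries, threshold: float = DARK_RADIATION):
    """Maximal half-open [start, end) intervals with radiation strictly below
    ``threshold``; ``end`` is the first timestamp back at or above it."""
    f = meteo.frame
    dark = f["radiation"].to_numpy(float) < threshold
    if not dark.any():
        return []
    edges = np.diff(dark.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if dark[0]:
        starts.insert(0, 0)
    if dark[-1]:
        ends.append(len(dark))
    idx = f.index
    step = idx[1] - idx[0] if len(idx) > 1 else pd.Timedelta(minutes=1)
    out = []
    for s, e in zip(starts, ends):
        end_ts = idx[e] if e < len(idx) else idx[-1] + step
        out.append((idx[s], end_ts))
    return out


def sample_correlation_matrix(log2rpm: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation between samples, each sample centred by its mean
    over genes; zero-variance samples yield NaN entries and are flagged."""
    Y = log2rpm.to_numpy(float)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    C = Y - Y.mean(axis=0, keepdims=True)
    denom = np.sqrt((C**2).sum(axis=0))
    zero = denom == 0
    denom_safe = np.where(zero, 1.0, denom)
    R = (C.T @ C) / np.outer(denom_safe, denom_safe)
    R[zero, :] = np.nan
    R[:, zero] = np.nan
    np.fill_diagonal(R, np.where(zero, np.nan, 1.0))
    R = np.clip(R, -1.0, 1.0, out=R)
    rho = pd.DataFrame(R, index=log2rpm.columns, columns=log2rpm.columns)
    return CorrelationMatrix(log2rpm.columns, rho, tuple(log2rpm.columns[zero]))


def preprocess_counts(
    counts: CountMatrix,
    meta: SampleMeta,
    heading_days: pd.Series,
    min_total: int = MIN_TOTAL_READS,
    max_detect_frac: float = MAX_DETECT_FRAC,
    genes: pd.Index = None,
) -> ExpressionData:
    """Filter, normalise and weight a raw count matrix.

    ``genes`` overrides the detection filter with a fixed analysis gene set —
    used when scoring a validation season against models trained on another
    season's gene list.
    """
    meta.require_samples(counts.sample_ids)
    keep_s = filter_samples(counts, min_total)
    cm = CountMatrix(counts.counts[keep_s])
    keep_g = filter_genes(cm, max_detect_frac) if genes is None else pd.Index(genes)
    cm = CountMatrix(cm.counts.loc[keep_g])
    y = to_log2rpm(cm)
    w = precision_weights(y)
    sub_meta = SampleMeta(meta.table.loc[keep_s].copy())
    sage = scaled_age(sub_meta, heading_days)
    return ExpressionData(y, w, sub_meta, sage)
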