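"""Synthetic study generator: genotype panels, weather, sampling schedules and
count matrices with the statistical structure the analysis assumes, plus the
planted ground truth needed for parameter-recovery tests.

The default configuration is desk-scale but structurally faithful to a
two-parent rice CSSL experiment: 12 chromosomes x 12 SSR markers, two parents,
80 single-segment substitution lines (40 per background, segments tiling the
genome), two mosaic backcross-inbred lines (~18 % donor genome), staggered
transplant sets, bihourly sampling days from 16:00 to 14:00 the next day, and
expression generated from planted parental clock/age/weather models with the
controlling marker deciding which parent's dynamics a line follows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data_io import CountMatrix, GenePositions, GenotypePanel, MeteoSeries, SampleMeta
from .envmodel import EnvFeatureSpec, env_features_matrix

BASE_DATE = pd.Timestamp("2015-05-01")


@dataclass
class SimConfig:
    # genome / panel
    n_chrom: int = 12
    markers_per_chrom: int = 12
    chrom_length_bp: int = 30_000_000
    n_cssl_per_background: int = 40
    n_bil: int = 2
    bil_substitution_frac: float = 0.18
    # genes; filler genes are high-abundance, non-polymorphic transcripts that
    # dominate library totals, as the unmodelled bulk transcriptome does in a
    # real study — without them, per-sample rpm normalisation on a small panel
    # would imprint a genotype-correlated compositional shift on every gene
    n_genes: int = 300
    n_filler_genes: int = 30
    filler_mu_range: tuple = (15.0, 17.0)
    frac_polymorphic: float = 0.20
    frac_trans_among_eqtl: float = 0.25
    frac_multi_eqtl: float = 0.0  # fraction of polymorphic genes driven by 2 loci
    # effect-size scales (log2 units)
    effect_mu: float = 2.0
    effect_clock: float = 1.0
    effect_age: float = 1.0
    effect_env: float = 1.0
    clock_prob: float = 0.6
    age_prob: float = 0.5
    env_prob: float = 0.5
    noise_sd: float = 0.5
    library_size_range: tuple = (3_000_000, 6_000_000)
    count_noise: str = "lognormal"  # or "nbinom"
    nb_dispersion: float = 0.05
    # season / schedule
    n_sampling_days: int = 8
    samples_per_day: int = 12  # bihourly time points per sampling day
    n_transplant_sets: int = 2
    season_span_days: int = 150
    sowing_interval_days: int = 14
    sampling_start_day: int = 30
    heading_mean_p1: float = 100.0
    heading_mean_p2: float = 90.0
    heading_sd: float = 3.0
    dropout_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chrom", "markers_per_chrom", "n_cssl_per_background",
                     "n_genes", "n_sampling_days", "samples_per_day", "n_transplant_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_polymorphic", "frac_trans_among_eqtl", "frac_multi_eqtl",
                     "bil_substitution_frac", "dropout_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.season_span_days < self.n_sampling_days:
            raise ValueError("season_span_days must cover n_sampling_days")


@dataclass
class GeneTruth:
    gene_id: str
    polymorphic: bool
    cis_trans: str  # 'cis' | 'trans' | ''
    markers: tuple  # controlling markers (empty when non-polymorphic)
    params_p1: dict
    params_p2: dict


@dataclass
class SimTruth:
    genes: dict  # gene_id -> GeneTruth
    segments: dict  # line_id -> list of (marker_start_idx, marker_end_idx) donor runs
    latent: Optional[pd.DataFrame] = None  # genes x samples latent log2rpm

    def to_json(self, path) -> None:
        payload = {
            "genes": {
                g: {
                    "polymorphic": t.polymorphic,
                    "cis_trans": t.cis_trans,
                    "markers": list(t.markers),
                    "params_p1": _spec_to_json(t.params_p1),
                    "params_p2": _spec_to_json(t.params_p2),
                }
                for g, t in self.genes.items()
            },
            "segments": {l: [list(map(int, s)) for s in segs] for l, segs in self.segments.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _spec_to_json(params: dict) -> dict:
    out = dict(params)
    spec = out.get("env_spec")
    if spec is not None:
        out["env_spec"] = [spec.variable, spec.window_hours, spec.gate_threshold]
    return out


def _spec_from_json(params: dict) -> dict:
    out = dict(params)
    if out.get("env_spec") is not None:
        var, w, theta = out["env_spec"]
        out["env_spec"] = EnvFeatureSpec(var, float(w), float(theta))
    return out


def truth_from_json(path) -> SimTruth:
    """Rebuild planted truth from ``truth.json`` (latent matrix is not stored)."""
    with open(path) as fh:
        payload = json.load(fh)
    genes = {
        g: GeneTruth(
            g,
            d["polymorphic"],
            d["cis_trans"],
            tuple(d["markers"]),
            _spec_from_json(d["params_p1"]),
            _spec_from_json(d["params_p2"]),
        )
        for g, d in payload["genes"].items()
    }
    segments = {l: [tuple(s) for s in segs] for l, segs in payload["segments"].items()}
    return SimTruth(genes=genes, segments=segments)


@dataclass
class SimBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    panel: GenotypePanel
    meteo: MeteoSeries
    meta: SampleMeta
    counts: CountMatrix
    gene_positions: GenePositions
    truth: SimTruth
    bil_lines: tuple


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator):
    """Two parents, a tiling single-segment CSSL panel per background and
    random contiguous-block mosaic BILs near the target substitution fraction."""
    M = cfg.n_chrom * cfg.markers_per_chrom
    marker_ids = []
    chroms = []
    pos = []
    for c in range(cfg.n_chrom):
        for i in range(cfg.markers_per_chrom):
            marker_ids.append(f"M{c + 1:02d}_{i + 1:02d}")
            chroms.append(f"chr{c + 1:02d}")
            pos.append(int((i + 0.5) * cfg.chrom_length_bp / cfg.markers_per_chrom))
    marker_map = pd.DataFrame({"chrom": chroms, "pos_bp": pos}, index=pd.Index(marker_ids, name="marker_id"))

    # distribute CSSL segments across chromosomes, contiguous within a chromosome
    n_cssl = cfg.n_cssl_per_background
    per_chrom = np.full(cfg.n_chrom, n_cssl // cfg.n_chrom)
    per_chrom[: n_cssl % cfg.n_chrom] += 1
    if per_chrom.max() > cfg.markers_per_chrom:
        raise ValueError("markers_per_chrom too small to tile the requested CSSL count")
    segments = []  # (start, end) global marker index, half-open
    for c in range(cfg.n_chrom):
        if per_chrom[c] == 0:
            continue
        base = c * cfg.markers_per_chrom
        splits = np.array_split(np.arange(cfg.markers_per_chrom), per_chrom[c])
        for s in splits:
            segments.append((base + int(s[0]), base + int(s[-1]) + 1))

    lines = ["P1", "P2"]
    rows = {"P1": np.full(M, "P1", dtype=object), "P2": np.full(M, "P2", dtype=object)}
    seg_by_line: dict = {"P1": [], "P2": []}
    for bg, donor, prefix in (("P1", "P2", "C1"), ("P2", "P1", "C2")):
        for k, (s, e) in enumerate(segments):
            lid = f"{prefix}_{k + 1:02d}"
            alle = np.full(M, bg, dtype=object)
            alle[s:e] = donor
            rows[lid] = alle
            seg_by_line[lid] = [(s, e)]
            lines.append(lid)
    # BILs: donor blocks dropped in until the realized fraction reaches target
    for b in range(cfg.n_bil):
        lid = f"B{b + 1}"
        bg, donor = "P2", "P1"
        alle = np.full(M, bg, dtype=object)
        target = int(round(cfg.bil_substitution_frac * M))
        # hard ceiling keeps the realised fraction within ~5 points of target
        max_total = max(target, int(np.floor((cfg.bil_substitution_frac + 0.045) * M)))
        runs = []
        guard = 0
        while (alle == donor).sum() < target and guard < 1000:
            guard += 1
            c = int(rng.integers(cfg.n_chrom))
            length = int(min(rng.geometric(1 / 5.0), cfg.markers_per_chrom))
            start = int(rng.integers(cfg.markers_per_chrom - length + 1))
            s = c * cfg.markers_per_chrom + start
            if (alle[s: s + length] == donor).any():
                continue
            if (alle == donor).sum() + length > max_total:
                continue
            alle[s: s + length] = donor
            runs.append((s, s + length))
        rows[lid] = alle
        seg_by_line[lid] = sorted(runs)
        lines.append(lid)
    alleles = pd.DataFrame(
        np.stack([rows[l] for l in lines]), index=pd.Index(lines, name="line_id"), columns=marker_ids
    )
    panel = GenotypePanel(alleles, marker_map)
    return panel, seg_by_line


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------


def simulate_meteo(
    cfg: SimConfig,
    seed: int = 0,
    temp_offset: float = 0.0,
    start: pd.Timestamp = None,
) -> MeteoSeries:
    """Minute-resolution season: temperature = seasonal trend + diurnal sinusoid
    + slow AR(1) noise; radiation = daylight half-sinusoid x daily cloud factor,
    exactly zero at night."""
    rng = np.random.default_rng(seed)
    t0 = (start or BASE_DATE) - pd.Timedelta(days=4)  # head margin for long windows
    n_days = cfg.season_span_days + 6
    n = n_days * 1440
    minutes = np.arange(n)
    day = minutes / 1440.0
    hour = (minutes % 1440) / 60.0
    season = 18.0 + 8.0 * np.sin(np.pi * np.clip(day - 4, 0, cfg.season_span_days) / cfg.season_span_days)
    diurnal = 5.0 * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    phi = 0.999
    innov = rng.normal(0.0, np.sqrt(1 - phi**2), n)
    ar = lfilter([1.0], [1.0, -phi], innov)
    temperature = season + diurnal + 1.0 * ar + temp_offset

    daylength = 12.0 + 2.2 * np.sin(np.pi * np.clip(day - 4, 0, cfg.season_span_days) / cfg.season_span_days)
    sunrise = 12.0 - daylength / 2.0
    phase = (hour - sunrise) / daylength
    base = np.where((phase > 0) & (phase < 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    cloud = rng.beta(4.0, 2.0, n_days)[minutes // 1440]
    radiation = 3.3 * base * cloud
    radiation[base <= 0] = 0.0

    idx = pd.date_range(t0, periods=n, freq="1min")
    return MeteoSeries(pd.DataFrame({"temperature": temperature, "radiation": radiation}, index=idx))


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def sampling_day_numbers(cfg: SimConfig) -> np.ndarray:
    lo = cfg.sampling_start_day
    hi = cfg.season_span_days - 2
    return np.unique(np.round(np.linspace(lo, hi, cfg.n_sampling_days)).astype(int))


def simulate_schedule(cfg: SimConfig, panel: GenotypePanel, rng: np.random.Generator,
                      day_numbers=None, start: pd.Timestamp = None):
    """Bihourly sampling days (16:00 through 14:00 the next day), each (line,
    transplant set) sampled at most once per day, time points dealt by a
    stratified shuffle so per-line totals stay balanced.  Also draws a heading
    day per (line, set) around the background parent's mean and attaches it to
    the panel."""
    base = start or BASE_DATE
    days = sampling_day_numbers(cfg) if day_numbers is None else np.asarray(day_numbers)
    lines = list(panel.line_ids)
    offsets_h = [16 + 2 * i for i in range(cfg.samples_per_day)]  # hours from day start
    heading = {}
    for line in lines:
        mean = cfg.heading_mean_p1 if panel.background[line] == "P1" else cfg.heading_mean_p2
        for tset in range(1, cfg.n_transplant_sets + 1):
            heading[(line, tset)] = max(30.0, mean + rng.normal(0.0, cfg.heading_sd))
    rows = []
    counter = 0
    n_days = len(days)
    for rank, d in enumerate(days):
        for tset in range(1, cfg.n_transplant_sets + 1):
            sow_day = (tset - 1) * cfg.sowing_interval_days
            order = rng.permutation(len(lines))
            for slot, li in enumerate(order):
                line = lines[li]
                if cfg.dropout_frac > 0 and n_days > 1:
                    p_drop = cfg.dropout_frac * rank / (n_days - 1)
                    if rng.random() < p_drop:
                        continue
                t = base + pd.Timedelta(days=int(d), hours=offsets_h[slot % cfg.samples_per_day])
                counter += 1
                rows.append(
                    {
                        "sample_id": f"S{counter:05d}",
                        "line_id": line,
                        "transplant_set": tset,
                        "sowing_date": base + pd.Timedelta(days=sow_day),
                        "sampling_time": t,
                        "site_id": "simfield",
                    }
                )
    meta = SampleMeta(pd.DataFrame(rows).set_index("sample_id"))
    hs = pd.Series(heading)
    hs.index.names = ["line_id", "transplant_set"]
    panel.heading_days = hs
    return meta


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_GEN_WINDOWS = (1.0, 2.0, 4.0, 8.0, 24.0)
_GEN_QUANTILES = (0.0, 0.25, 0.5, 0.75)


def _gene_positions(cfg: SimConfig, rng: np.random.Generator, gene_ids):
    chrom = rng.integers(cfg.n_chrom, size=len(gene_ids))
    pos = rng.integers(1, cfg.chrom_length_bp, size=len(gene_ids))
    return GenePositions(
        pd.DataFrame(
            {"chrom": [f"chr{c + 1:02d}" for c in chrom], "pos_bp": pos},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )


def _nearest_marker(panel: GenotypePanel, chrom: str, pos: int) -> str:
    mm = panel.marker_map
    sub = mm[mm["chrom"] == chrom]
    return sub.index[np.argmin(np.abs(sub["pos_bp"].to_numpy() - pos))]


def _draw_params(cfg, rng, spec_pool, env_sd):
    params = {"mu": float(rng.uniform(3.0, 9.0)), "a": 0.0, "b": 0.0, "c": 0.0,
              "d": 0.0, "env_spec": None}
    if rng.random() < cfg.clock_prob:
        amp = rng.uniform(0.5, 2.0) * cfg.effect_clock
        phase = rng.uniform(0, 2 * np.pi)
        params["a"], params["b"] = amp * np.cos(phase), amp * np.sin(phase)
    if rng.random() < cfg.age_prob:
        params["c"] = float(rng.choice([-1, 1]) * rng.uniform(0.5, 2.0) * cfg.effect_age)
    if rng.random() < cfg.env_prob:
        j = int(rng.integers(len(spec_pool)))
        if env_sd[j] > 1e-6:
            target = rng.uniform(0.5, 1.5) * cfg.effect_env
            params["env_spec"] = spec_pool[j]
            params["d"] = float(rng.choice([-1, 1]) * target / env_sd[j])
    return params


def simulate_expression(
    panel: GenotypePanel,
    meteo: MeteoSeries,
    meta: SampleMeta,
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: SimTruth = None,
    gene_positions: GenePositions = None,
):
    """Counts from planted parental models.  When ``truth`` is given (a
    validation season) the planted parameters and eQTL assignments are reused
    and only the noise, library sizes and features are redrawn."""
    samples = meta.table
    n_s = len(samples)
    sage = _scaled_age_from(meta, panel.heading_days)
    spec_pool = _spec_pool(meteo)
    if truth is not None:
        # a validation season: features are needed for the planted specs, which
        # were drawn from the training season's gate quantiles
        needed = {p["env_spec"] for t in truth.genes.values()
                  for p in (t.params_p1, t.params_p2) if p["env_spec"] is not None}
        spec_pool = sorted(set(spec_pool) | needed,
                           key=lambda s: (s.variable, s.window_hours, s.gate_threshold))
    F = env_features_matrix(meteo, samples["sampling_time"].to_numpy(), spec_pool)
    env_sd = F.std(axis=0)

    if truth is None:
        gene_ids = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
        filler_ids = [f"f{i + 1:03d}" for i in range(cfg.n_filler_genes)]
        if gene_positions is None:
            gene_positions = _gene_positions(cfg, rng, gene_ids + filler_ids)
        n_poly = int(round(cfg.frac_polymorphic * cfg.n_genes))
        poly_idx = set(rng.choice(cfg.n_genes, size=n_poly, replace=False).tolist())
        genes = {}
        for i, g in enumerate(gene_ids):
            p1 = _draw_params(cfg, rng, spec_pool, env_sd)
            poly = i in poly_idx
            markers: tuple = ()
            ct = ""
            if poly:
                p2 = dict(p1)
                p2["mu"] = p1["mu"] + float(rng.choice([-1, 1])) * cfg.effect_mu
                if rng.random() < 0.5 and p1["a"] != 0.0:
                    shrink = rng.uniform(0.2, 0.6)
                    p2["a"], p2["b"] = p1["a"] * shrink, p1["b"] * shrink
                gp = gene_positions.table.loc[g]
                if rng.random() < cfg.frac_trans_among_eqtl:
                    ct = "trans"
                    others = panel.marker_map[panel.marker_map["chrom"] != gp["chrom"]]
                    primary = others.index[int(rng.integers(len(others)))]
                else:
                    ct = "cis"
                    primary = _nearest_marker(panel, gp["chrom"], int(gp["pos_bp"]))
                markers = (primary,)
                if rng.random() < cfg.frac_multi_eqtl:
                    # a second locus on another chromosome; either substituted
                    # locus switches the gene to the donor parent's dynamics
                    others = panel.marker_map[
                        panel.marker_map["chrom"]
                        != panel.marker_map.loc[primary, "chrom"]
                    ]
                    markers = (primary, others.index[int(rng.integers(len(others)))])
            else:
                p2 = dict(p1)
            genes[g] = GeneTruth(g, poly, ct, markers, p1, p2)
        for g in filler_ids:
            pf = {"mu": float(rng.uniform(*cfg.filler_mu_range)), "a": 0.0, "b": 0.0,
                  "c": 0.0, "d": 0.0, "env_spec": None}
            genes[g] = GeneTruth(g, False, "", (), pf, dict(pf))
        gene_ids = gene_ids + filler_ids
        truth = SimTruth(genes=genes, segments={})
    else:
        gene_ids = list(truth.genes)
        if gene_positions is None:
            gene_positions = _gene_positions(cfg, rng, gene_ids)

    # model value per sample for each parent, then pick by controlling markers
    cosv, sinv = _clock(samples)
    lat = np.empty((len(gene_ids), n_s))
    line_arr = samples["line_id"].to_numpy()
    line_pos = panel.line_ids.get_indexer(line_arr)
    alleles = panel.alleles.to_numpy()
    bg_is_p2 = (panel.background.to_numpy() == "P2")
    col_of = {m: j for j, m in enumerate(panel.marker_ids)}
    spec_idx = {s: j for j, s in enumerate(spec_pool)}
    for gi, g in enumerate(gene_ids):
        t = truth.genes[g]
        vals = {}
        for pname, pp in (("P1", t.params_p1), ("P2", t.params_p2)):
            v = pp["mu"] + pp["a"] * cosv + pp["b"] * sinv + pp["c"] * sage
            if pp["env_spec"] is not None:
                v = v + pp["d"] * F[:, spec_idx[pp["env_spec"]]]
            vals[pname] = v
        if t.polymorphic:
            cols = [col_of[m] for m in t.markers]
            if len(cols) == 1:
                use_p2_line = alleles[:, cols[0]] == "P2"
            else:
                # multi-locus rule: any non-background allele at a controlling
                # locus switches the line to the donor parent's dynamics
                is_p2 = alleles[:, cols] == "P2"
                nonbg = (is_p2 != bg_is_p2[:, None]).any(axis=1)
                use_p2_line = np.where(nonbg, ~bg_is_p2, bg_is_p2)
            use_p2 = use_p2_line[line_pos]
        else:
            use_p2 = bg_is_p2[line_pos]
        lat[gi] = np.where(use_p2, vals["P2"], vals["P1"])
    latent_clean = lat.copy()
    lat = lat + rng.normal(0.0, cfg.noise_sd, size=lat.shape)

    lib = rng.uniform(*cfg.library_size_range, size=n_s)
    mean_counts = np.maximum(np.exp2(lat) - 1.0, 0.0) * (lib / 1e6)[None, :]
    if cfg.count_noise == "nbinom":
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + np.maximum(mean_counts, 1e-9)))
    else:
        counts = np.rint(mean_counts).astype(np.int64)
    cm = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=pd.Index(gene_ids, name="gene_id"),
                     columns=samples.index)
    )
    truth.latent = pd.DataFrame(latent_clean, index=cm.counts.index, columns=cm.counts.columns)
    return cm, truth, gene_positions


def _clock(samples: pd.DataFrame):
    ts = pd.DatetimeIndex(samples["sampling_time"])
    h = ts.hour + ts.minute / 60.0
    ang = 2 * np.pi * np.asarray(h) / 24.0
    return np.cos(ang), np.sin(ang)


def _scaled_age_from(meta: SampleMeta, heading: pd.Series) -> np.ndarray:
    t = meta.table
    days = (t["sampling_time"] - t["sowing_date"]) / pd.Timedelta(days=1)
    hd = heading.loc[list(zip(t["line_id"], t["transplant_set"]))].to_numpy()
    return days.to_numpy() / hd


def _spec_pool(meteo: MeteoSeries):
    pool = []
    for var in ("temperature", "radiation"):
        x = meteo.frame[var].to_numpy(float)
        thetas = sorted({round(float(np.quantile(x, q)), 6) for q in _GEN_QUANTILES})
        for theta in thetas:
            for w in _GEN_WINDOWS:
                pool.append(EnvFeatureSpec(var, w, theta))
    return pool


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------


def simulate_bundle(cfg: SimConfig) -> SimBundle:
    """Full study under one seed: panel, weather, schedule, counts, truth."""
    root = np.random.SeedSequence(cfg.seed)
    s_geno, s_meteo, s_sched, s_expr = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)]
    panel, segments = simulate_genotypes(cfg, np.random.default_rng(s_geno))
    meteo = simulate_meteo(cfg, seed=s_meteo)
    meta = simulate_schedule(cfg, panel, np.random.default_rng(s_sched))
    counts, truth, gene_pos = simulate_expression(
        panel, meteo, meta, cfg, np.random.default_rng(s_expr)
    )
    truth.segments = segments
    bil_lines = tuple(l for l in panel.line_ids if l.startswith("B"))
    return SimBundle(cfg, panel, meteo, meta, counts, gene_pos, truth, bil_lines)


def simulate_validation_bundle(
    bundle: SimBundle,
    seed: int,
    temp_offset: float = 2.0,
    n_days: int = 4,
) -> SimBundle:
    """A second season for the same panel and planted truth: new weather trend
    and seed, a fresh (shorter) schedule, fresh noise and library sizes."""
    cfg = bundle.config
    root = np.random.SeedSequence(seed)
    s_meteo, s_sched, s_expr = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)]
    start_b = BASE_DATE + pd.Timedelta(days=366)
    meteo = simulate_meteo(cfg, seed=s_meteo, temp_offset=temp_offset, start=start_b)
    days = np.round(np.linspace(cfg.sampling_start_day, cfg.season_span_days - 2, n_days)).astype(int)
    rng = np.random.default_rng(s_sched)
    heading_saved = bundle.panel.heading_days
    meta = simulate_schedule(cfg, bundle.panel, rng, day_numbers=days, start=start_b)
    bundle.panel.heading_days = heading_saved  # keep the training-season headings
    truth_b = SimTruth(genes=bundle.truth.genes, segments=bundle.truth.segments)
    counts, truth_b, _ = simulate_expression(
        bundle.panel, meteo, meta, cfg, np.random.default_rng(s_expr),
        truth=truth_b, gene_positions=bundle.gene_positions,
    )
    return SimBundle(cfg, bundle.panel, meteo, meta, counts, bundle.gene_positions,
                     truth_b, bundle.bil_lines)
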