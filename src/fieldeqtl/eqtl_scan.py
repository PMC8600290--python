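"""Marker scan for eQTLs governing expression dynamics.

For each gene flagged as dynamically polymorphic between the parents, every
marker proposes an assignment: samples of lines carrying the P1 allele are
predicted with the P1 parental model, P2-allele lines with the P2 model.  The
scan statistic is the drop in weighted prediction residual error relative to
the background-genotype assignment, T_m = RSS_BG - RSS_m.  Significance comes
from permuting marker alleles across lines (samples travel with their line):
per-marker empirical p-values, and a per-gene genome-wide maximum-T null used
to call genes at FDR 0.05 (Benjamini-Hochberg across genes).  Within a called
gene, markers exceeding the 95th percentile of the max-T null are grouped into
blocks of contiguous markers with identical assignment signatures — linked
markers inside one substituted segment are mathematically indistinguishable —
and each block yields one call.  Calls are labelled cis when the representative
marker sits within a window of the gene on the same chromosome, and several
blocks can be combined by forward selection when their joint assignment
strictly lowers the residual error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from .stats import bh_adjust

from .data_io import GenePositions, GenotypePanel
from .envmodel import FitContext, GeneModel, model_columns, _coef_vector

CIS_WINDOW_BP = 2_000_000
GENOME_WIDE_QUANTILE = 0.95


@dataclass
class Assignment:
    """Which parental model predicts each sample (or line)."""

    by_line: pd.Series  # line_id -> 'P1' | 'P2'
    by_sample: pd.Series = None  # sample_id -> 'P1' | 'P2' (when sample lines given)


@dataclass
class ScanProfile:
    gene_id: str
    marker_ids: pd.Index
    rss: np.ndarray  # weighted residual-error sum per marker assignment
    T: np.ndarray  # RSS_BG - rss
    rss_bg: float
    line_ids: pd.Index
    e_p1: np.ndarray  # per-line weighted error totals under the P1 model
    e_p2: np.ndarray


@dataclass
class ScanPermutations:
    gene_id: str
    marker_p: np.ndarray
    gene_p: float
    null_max: np.ndarray  # genome-wide max-T per permutation
    n_perm: int


@dataclass
class EqtlCall:
    gene_id: str
    block_markers: tuple
    representative: str
    chrom: str
    pos_start: int
    pos_end: int
    statistic: float
    p: float
    q: float
    rep_pos: int = -1
    cis_trans: str = "unknown"
    multi_eqtl: tuple = ()
    combined_rss: float = np.nan


def assignment_from_marker(panel: GenotypePanel, marker: str, sample_lines: pd.Series = None) -> Assignment:
    """Each line follows the parental model matching its allele at ``marker``."""
    if marker not in panel.marker_ids:
        raise KeyError(f"unknown marker {marker!r}")
    by_line = panel.alleles[marker].copy()
    by_sample = None
    if sample_lines is not None:
        by_sample = pd.Series(
            by_line.loc[sample_lines.to_numpy()].to_numpy(), index=sample_lines.index
        )
    return Assignment(by_line=by_line, by_sample=by_sample)


def _per_line_errors(y, w, model_p1: GeneModel, model_p2: GeneModel, ctx: FitContext,
                     line_codes: np.ndarray, n_lines: int):
    """Per-line totals of w*(y - yhat)^2 under each parental model."""
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    out = []
    for model in (model_p1, model_p2):
        cols = model_columns(model, ctx)
        yhat = ctx.X[:, cols] @ _coef_vector(model)
        err = w * (y - yhat) ** 2
        out.append(np.bincount(line_codes, weights=err, minlength=n_lines))
    return out


def scan_gene(
    y,
    w,
    model_p1: GeneModel,
    model_p2: GeneModel,
    panel: GenotypePanel,
    ctx: FitContext,
    sample_lines: pd.Series,
    gene_id: str = "",
) -> ScanProfile:
    """Residual-error profile over all markers for one gene.

    ``ctx`` covers the analysed samples; ``sample_lines`` maps them to panel
    lines (parents + CSSLs).  Predictions are computed once per parent and
    reused for every marker.
    """
    lines = pd.Index(sorted(set(sample_lines)))
    line_codes = lines.get_indexer(sample_lines.to_numpy())
    e1, e2 = _per_line_errors(y, w, model_p1, model_p2, ctx, line_codes, len(lines))
    A = (panel.alleles.loc[lines].to_numpy() == "P2").astype(float)  # lines x markers
    rss = e1 @ (1.0 - A) + e2 @ A
    bg_p2 = (panel.background.loc[lines].to_numpy() == "P2").astype(float)
    rss_bg = float(e1 @ (1.0 - bg_p2) + e2 @ bg_p2)
    return ScanProfile(
        gene_id=gene_id,
        marker_ids=panel.marker_ids,
        rss=rss,
        T=rss_bg - rss,
        rss_bg=rss_bg,
        line_ids=lines,
        e_p1=e1,
        e_p2=e2,
    )


def stratified_permutations(background: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Line-index permutations restricted to within-background shuffles.

    Allele columns in a substitution-line panel are strongly aligned with the
    background split (every line carries its background allele outside its
    donor segment).  Unrestricted permutation therefore destroys that
    alignment and yields a null of wholesale misassignment that no observed
    marker resembles; exchangeability under 'no eQTL here' holds for *which
    lines of a background carry the donor segment*, i.e. within strata."""
    L = len(background)
    out = np.tile(np.arange(L), (n_perm, 1))
    for bg in np.unique(background):
        pos = np.nonzero(background == bg)[0]
        for p in range(n_perm):
            out[p, pos] = pos[rng.permutation(len(pos))]
    return out


def permutation_pvalues(
    profile: ScanProfile,
    panel: GenotypePanel,
    n_perm: int = 200,
    seed: int = 0,
    perm_idx: np.ndarray = None,
) -> ScanPermutations:
    """Null by permuting each marker's allele column across lines, within
    background strata (see :func:`stratified_permutations`).

    p_m = (1 + #{T_null >= T_m}) / (n_perm + 1).  One shared set of line
    permutations drives all markers, which additionally yields the genome-wide
    maximum-T null used for gene-level calling.  The max-T gene p is
    conservative under a strong true effect: a permutation relocates the
    causal line's entire error profile onto another line, whose donor segment
    then reproduces the observed T at *its* markers, so the null maximum
    regenerates the effect with probability ~1/(number of segments per
    background).  At panel scale (~40 segments) this floor sits well below
    the BH threshold of the polymorphism-filtered gene set; it is the price
    of an exact line-level permutation null.  Markers at which every line
    carries the same allele are degenerate and get p = 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if perm_idx is None:
        rng = np.random.default_rng(seed)
        bg = panel.background.loc[profile.line_ids].to_numpy()
        perm_idx = stratified_permutations(bg, n_perm, rng)
    else:
        n_perm = perm_idx.shape[0]
    A = (panel.alleles.loc[profile.line_ids].to_numpy() == "P2").astype(float)
    E1 = profile.e_p1[perm_idx]  # n_perm x L
    E2 = profile.e_p2[perm_idx]
    rss_null = E1 @ (1.0 - A) + E2 @ A
    T_null = profile.rss_bg - rss_null
    ge = T_null >= profile.T[None, :] - 1e-12
    p = (1.0 + ge.sum(axis=0)) / (n_perm + 1.0)
    degenerate = (A == A[0]).all(axis=0)
    p[degenerate] = 1.0
    informative = ~degenerate
    if informative.any():
        null_max = T_null[:, informative].max(axis=1)
        T_obs_max = profile.T[informative].max()
        gene_p = (1.0 + np.sum(null_max >= T_obs_max - 1e-12)) / (n_perm + 1.0)
    else:
        null_max = np.zeros(n_perm)
        gene_p = 1.0
    return ScanPermutations(profile.gene_id, p, float(gene_p), null_max, n_perm)


def _signature_blocks(panel: GenotypePanel, lines: pd.Index, sig_mask: np.ndarray):
    """Group flagged markers into runs of contiguous markers (same chromosome,
    adjacent in map order) with identical allele columns over ``lines``."""
    A = panel.alleles.loc[lines].to_numpy()
    chroms = panel.marker_map["chrom"].to_numpy()
    idx = np.nonzero(sig_mask)[0]
    blocks = []
    current: list[int] = []
    for j in idx:
        if current and (
            j != current[-1] + 1
            or chroms[j] != chroms[current[-1]]
            or not (A[:, j] == A[:, current[-1]]).all()
        ):
            blocks.append(current)
            current = []
        current.append(int(j))
    if current:
        blocks.append(current)
    return blocks


def call_eqtls(
    profiles: dict,
    perms: dict,
    panel: GenotypePanel,
    gene_positions: GenePositions = None,
    q_threshold: float = 0.05,
    cis_window_bp: int = CIS_WINDOW_BP,
) -> list[EqtlCall]:
    """Call eQTLs for genes whose genome-wide (max-T) permutation p clears
    ``q_threshold``; per called gene, one call per significant marker block;
    representative marker = max T (tie -> smallest position); multi-eQTL sets
    by forward selection.

    Error control is hierarchical: the scan is run on genes that already
    passed the parental-polymorphism test at FDR 0.05, and within each such
    gene the max-T permutation p is itself genome-wide corrected, so the
    per-gene decision is made at ``gene_p < q_threshold`` directly.  (BH on
    the gene p-values across genes is computed and reported as ``q`` on each
    call, but cannot drive the decision: the line-permutation p has an
    irreducible floor — the probability that a permutation relabels the
    causal lines onto another segment, ~1/(2 x number of segments) — which
    sits near the threshold, and BH over p-values clustered at a floor
    collapses to zero discoveries for small purity fluctuations.)"""
    genes = list(profiles)
    if not genes:
        return []
    gene_p = np.array([perms[g].gene_p for g in genes])
    gene_q = bh_adjust(gene_p)
    calls: list[EqtlCall] = []
    mm = panel.marker_map
    positions = mm["pos_bp"].to_numpy()
    chroms = mm["chrom"].to_numpy()
    for g, p, q in zip(genes, gene_p, gene_q):
        if p >= q_threshold:
            continue
        prof, perm = profiles[g], perms[g]
        thr = float(np.quantile(perm.null_max, GENOME_WIDE_QUANTILE))
        sig = (prof.T >= thr) & (prof.T > 0) & (perm.marker_p < 1.0)
        if not sig.any():
            # the gene passed FDR, so at least its best marker is reported
            sig = prof.T == prof.T.max()
        gene_calls = []
        for block in _signature_blocks(panel, prof.line_ids, sig):
            Tb = prof.T[block]
            best = [j for j in block if prof.T[j] >= Tb.max() - 1e-12]
            rep = min(best, key=lambda j: (positions[j]))
            gene_calls.append(
                EqtlCall(
                    gene_id=g,
                    block_markers=tuple(prof.marker_ids[j] for j in block),
                    representative=prof.marker_ids[rep],
                    chrom=str(chroms[rep]),
                    pos_start=int(positions[block[0]]),
                    pos_end=int(positions[block[-1]]),
                    statistic=float(prof.T[rep]),
                    p=float(p),
                    q=float(q),
                    rep_pos=int(positions[rep]),
                )
            )
        gene_calls.sort(key=lambda c: (-c.statistic, c.chrom, c.pos_start))
        selected, combined = multi_eqtl_selection(prof, gene_calls, panel)
        multi = tuple(c.representative for c in selected)
        for c in gene_calls:
            c.multi_eqtl = multi
            c.combined_rss = combined
            if gene_positions is not None:
                c.cis_trans = classify_cis_trans(c, gene_positions, cis_window_bp)
        calls.extend(gene_calls)
    return calls


def classify_cis_trans(call: EqtlCall, gene_positions: GenePositions,
                       cis_window_bp: int = CIS_WINDOW_BP) -> str:
    """cis iff the representative marker lies on the gene's chromosome within
    the window; unknown when the gene has no recorded position."""
    t = gene_positions.table
    if call.gene_id not in t.index:
        return "unknown"
    row = t.loc[call.gene_id]
    rep_pos = call.rep_pos if call.rep_pos >= 0 else call.pos_start
    return (
        "cis"
        if str(row["chrom"]) == call.chrom and abs(int(row["pos_bp"]) - rep_pos) <= cis_window_bp
        else "trans"
    )


def block_vote_p2(A_p2: np.ndarray, block_cols, rep_col: int) -> np.ndarray:
    """Per-line vote of one marker block: majority allele over the block's
    markers, ties resolved by the representative marker.  In the CSSL panel
    block members are identical by construction; in a mosaic (BIL) genome a
    recombination breakpoint may fall inside the block, and the consensus is
    the best available localisation of the eQTL."""
    votes = A_p2[:, block_cols].sum(axis=1)
    k = len(block_cols)
    out = votes * 2 > k
    tie = votes * 2 == k
    if tie.any():
        out = np.where(tie, A_p2[:, rep_col], out)
    return out.astype(bool)


def gene_assignment_p2(A_p2: np.ndarray, blocks: list, bg_p2: np.ndarray = None) -> np.ndarray:
    """Per-line parental assignment from the selected blocks of one gene.

    ``blocks`` is a list of (block_cols, rep_col), the max-T block first; each
    block votes its consensus allele via :func:`block_vote_p2`.  Across
    blocks, the non-background votes decide by majority: a line whose blocks
    all vote its own background allele keeps the background model, otherwise
    it follows the majority among the non-background votes — with two
    parental alleles that is simply the donor parent, so a single substituted
    block suffices.  (A genuine tie among non-background votes cannot arise
    in a biparental panel; the max-T block would break one.)  When ``bg_p2``
    is omitted every line's background is taken to be the majority of its own
    alleles across all markers."""
    votes = np.stack([block_vote_p2(A_p2, bc, rc) for bc, rc in blocks])  # blocks x lines
    if len(blocks) == 1:
        return votes[0].astype(bool)
    if bg_p2 is None:
        bg_p2 = A_p2.mean(axis=1) > 0.5
    nonbg = votes != bg_p2[None, :]
    return np.where(nonbg.any(axis=0), ~bg_p2, bg_p2).astype(bool)


def call_blocks(calls: list, marker_index: pd.Index) -> list:
    """(block_cols, rep_col) pairs for a gene's selected calls, max-T first."""
    ordered = sorted(calls, key=lambda c: (-c.statistic, c.chrom, c.pos_start))
    primary = ordered[0]
    selected = [c for c in ordered if not primary.multi_eqtl or c.representative in primary.multi_eqtl]
    col = {m: j for j, m in enumerate(marker_index)}
    return [
        (np.array([col[m] for m in c.block_markers]), col[c.representative])
        for c in (selected or [primary])
    ]


def multi_eqtl_selection(profile: ScanProfile, calls: list[EqtlCall], panel: GenotypePanel):
    """Forward selection over a gene's significant blocks, starting from the
    max-T call; a block is kept only when the combined assignment strictly
    lowers the weighted residual error."""
    if not calls:
        return [], np.nan
    A_p2 = panel.alleles.loc[profile.line_ids].to_numpy() == "P2"
    bg_p2 = panel.background.loc[profile.line_ids].to_numpy() == "P2"
    col_of = {m: j for j, m in enumerate(panel.marker_ids)}
    ordered = sorted(calls, key=lambda c: (-c.statistic, c.chrom, c.pos_start))

    def as_block(c: EqtlCall):
        return (np.array([col_of[m] for m in c.block_markers]), col_of[c.representative])

    def rss_of(cs):
        use_p2 = gene_assignment_p2(A_p2, [as_block(c) for c in cs], bg_p2)
        return float(np.where(use_p2, profile.e_p2, profile.e_p1).sum())

    selected = [ordered[0]]
    best = rss_of(selected)
    for cand in ordered[1:]:
        r = rss_of(selected + [cand])
        if r < best - 1e-12:
            selected.append(cand)
            best = r
    return selected, best


def scan_study(
    Y: pd.DataFrame,
    W: pd.DataFrame,
    models_p1: dict,
    models_p2: dict,
    panel: GenotypePanel,
    ctx: FitContext,
    sample_lines: pd.Series,
    genes=None,
    n_perm: int = 200,
    seed: int = 0,
):
    """Scan + permutations for a set of genes, sharing one permutation set."""
    genes = list(genes) if genes is not None else list(Y.index)
    rng = np.random.default_rng(seed)
    lines = pd.Index(sorted(set(sample_lines)))
    perm_idx = stratified_permutations(panel.background.loc[lines].to_numpy(), n_perm, rng)
    profiles, perms = {}, {}
    for g in genes:
        prof = scan_gene(
            Y.loc[g].to_numpy(), W.loc[g].to_numpy(), models_p1[g], models_p2[g],
            panel, ctx, sample_lines, gene_id=g,
        )
        profiles[g] = prof
        perms[g] = permutation_pvalues(prof, panel, perm_idx=perm_idx)
    return profiles, perms
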