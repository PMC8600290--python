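"""Readers, writers and validated containers for every table the pipeline touches.

All on-disk formats are plain text: TSV for count and result matrices, CSV for
genotypes, marker maps, gene positions, weather and sample metadata.  Timestamps
are ISO-8601 local time at minute resolution (single-site assumption, no
timezone arithmetic).  Alleles are coded categorically as ``P1``/``P2`` — never
0/1 integers — so a silent parent swap cannot survive a file round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ALLELES = ("P1", "P2")


class SchemaError(ValueError):
    """A file or table violates the schema; the message names the offending cell."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene-level read counts, genes x samples, non-negative integers."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise SchemaError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise SchemaError(f"duplicate sample id {dup!r}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            raise SchemaError("counts must be integers")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise SchemaError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class SampleMeta:
    """Per-sample metadata: line, transplant set, sowing date, sampling time, site."""

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("line_id", "transplant_set", "sowing_date", "sampling_time", "site_id")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise SchemaError(f"sample metadata missing columns {missing}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise SchemaError(f"duplicate sample id {dup!r}")
        t["sowing_date"] = pd.to_datetime(t["sowing_date"])
        t["sampling_time"] = pd.to_datetime(t["sampling_time"])
        bad = t.index[t["sampling_time"] <= t["sowing_date"]]
        if len(bad):
            raise SchemaError(f"sample {bad[0]!r} sampled on or before its sowing date")

    def require_samples(self, sample_ids) -> None:
        missing = pd.Index(sample_ids).difference(self.table.index)
        if len(missing):
            raise SchemaError(f"sample {missing[0]!r} has no metadata row")


@dataclass
class GenotypePanel:
    """Line x marker allele table with a physical marker map.

    ``alleles`` holds "P1"/"P2" strings, lines in rows, markers in columns in
    map order (sorted by chromosome then position).  ``background`` maps each
    line to its recurrent parent; for a CSSL or BIL this is the majority
    allele.  ``heading_days`` maps (line, transplant_set) to days from sowing
    to heading and may be attached after construction.
    """

    alleles: pd.DataFrame
    marker_map: pd.DataFrame  # indexed by marker_id, columns chrom, pos_bp
    background: pd.Series = None
    heading_days: pd.Series = None  # MultiIndex (line_id, transplant_set)

    def __post_init__(self) -> None:
        mm = self.marker_map
        if not {"chrom", "pos_bp"}.issubset(mm.columns):
            raise SchemaError("marker map needs 'chrom' and 'pos_bp' columns")
        missing = self.alleles.columns.difference(mm.index)
        if len(missing):
            raise SchemaError(f"marker {missing[0]!r} missing from the marker map")
        if mm.duplicated(["chrom", "pos_bp"]).any():
            dup = mm.index[mm.duplicated(["chrom", "pos_bp"])][0]
            raise SchemaError(f"marker {dup!r} duplicates a (chrom, pos) pair")
        # sort markers by (chrom, pos); restrict the map to genotyped markers
        mm = mm.loc[self.alleles.columns].sort_values(["chrom", "pos_bp"])
        self.marker_map = mm
        self.alleles = self.alleles[mm.index]
        vals = self.alleles.to_numpy()
        bad = ~np.isin(vals, ALLELES)
        if bad.any():
            l, m = np.argwhere(bad)[0]
            raise SchemaError(
                f"allele {vals[l, m]!r} at line {self.alleles.index[l]!r}, "
                f"marker {self.alleles.columns[m]!r} is not P1/P2"
            )
        if self.alleles.isna().any().any():
            raise SchemaError("missing genotype cells are not supported; pre-impute")
        if self.background is None:
            is_p2 = (vals == "P2").mean(axis=1)
            self.background = pd.Series(
                np.where(is_p2 > 0.5, "P2", "P1"), index=self.alleles.index
            )

    @property
    def line_ids(self) -> pd.Index:
        return self.alleles.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.alleles.columns


@dataclass
class MeteoSeries:
    """Minute- (or coarser-) resolution weather: air temperature and solar radiation."""

    frame: pd.DataFrame  # DatetimeIndex; columns temperature (degC), radiation (kJ/m2/min)

    def __post_init__(self) -> None:
        f = self.frame
        if not {"temperature", "radiation"}.issubset(f.columns):
            raise SchemaError("weather table needs 'temperature' and 'radiation'")
        if f.index.has_duplicates:
            raise SchemaError(f"duplicate weather timestamp {f.index[f.index.duplicated()][0]}")
        if not f.index.is_monotonic_increasing:
            raise SchemaError("weather timestamps must be strictly increasing")
        if (f["radiation"].to_numpy() < 0).any():
            t = f.index[f["radiation"].to_numpy() < 0][0]
            raise SchemaError(f"negative radiation at {t}")

    def covers(self, start, end) -> bool:
        return self.frame.index[0] <= pd.Timestamp(start) and pd.Timestamp(end) <= self.frame.index[-1]


@dataclass
class GenePositions:
    table: pd.DataFrame  # indexed by gene_id, columns chrom, pos_bp

    def __post_init__(self) -> None:
        if not {"chrom", "pos_bp"}.issubset(self.table.columns):
            raise SchemaError("gene position table needs 'chrom' and 'pos_bp'")
        if (self.table["pos_bp"].to_numpy() <= 0).any():
            g = self.table.index[self.table["pos_bp"].to_numpy() <= 0][0]
            raise SchemaError(f"non-positive position for gene {g!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_counts(path) -> CountMatrix:
    """Read a TSV count matrix: header row of sample ids, first column gene ids."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as err:  # ragged rows etc.
        raise SchemaError(f"malformed count file {path}: {err}") from err
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], downcast=None)
        except (ValueError, TypeError) as err:
            raise SchemaError(f"malformed number in column {col!r}: {err}") from err
        if not np.issubdtype(df[col].dtype, np.integer):
            frac = df[col].to_numpy() % 1
            if (frac != 0).any():
                row = df.index[np.nonzero(frac)[0][0]]
                raise SchemaError(f"non-integer count at gene {row!r}, sample {col!r}")
            df[col] = df[col].astype(np.int64)
    return CountMatrix(df.astype(np.int64))


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_meta(path) -> SampleMeta:
    df = pd.read_csv(path, index_col="sample_id")
    return SampleMeta(df)


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.table.to_csv(path, index_label="sample_id")


def read_genotypes(path_alleles, path_map, path_heading=None) -> GenotypePanel:
    """Read an allele CSV (lines x markers) plus a marker map CSV (marker, chrom, pos_bp)."""
    alleles = pd.read_csv(path_alleles, index_col=0)
    mm = pd.read_csv(path_map, index_col="marker_id")
    panel = GenotypePanel(alleles, mm)
    if path_heading is not None:
        panel.heading_days = read_heading_days(path_heading)
    return panel


def write_genotypes(panel: GenotypePanel, path_alleles, path_map, path_heading=None) -> None:
    panel.alleles.to_csv(path_alleles, index_label="line_id")
    panel.marker_map.to_csv(path_map, index_label="marker_id")
    if path_heading is not None and panel.heading_days is not None:
        write_heading_days(panel.heading_days, path_heading)


def read_heading_days(path) -> pd.Series:
    df = pd.read_csv(path)
    s = df.set_index(["line_id", "transplant_set"])["heading_days"].astype(float)
    if (s <= 0).any():
        raise SchemaError("heading_days must be positive")
    return s


def write_heading_days(heading: pd.Series, path) -> None:
    heading.rename("heading_days").reset_index().to_csv(path, index=False)


def read_meteo(path) -> MeteoSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
    return MeteoSeries(df)


def write_meteo(meteo: MeteoSeries, path) -> None:
    meteo.frame.to_csv(path, index_label="timestamp")


def read_gene_positions(path) -> GenePositions:
    df = pd.read_csv(path, index_col="gene_id")
    return GenePositions(df)


def write_gene_positions(gp: GenePositions, path) -> None:
    gp.table.to_csv(path, index_label="gene_id")


RESULT_COLUMNS = (
    "gene",
    "marker_block",
    "chrom",
    "pos_span",
    "statistic",
    "p",
    "q",
    "cis_trans",
    "n_markers_in_block",
)


def write_results(calls, path) -> None:
    """Write eQTL calls as a TSV, deterministically ordered by gene then (chrom, pos)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene": c.gene_id,
                "marker_block": ";".join(c.block_markers),
                "chrom": c.chrom,
                "pos_span": f"{c.pos_start}-{c.pos_end}",
                "statistic": c.statistic,
                "p": c.p,
                "q": c.q,
                "cis_trans": c.cis_trans,
                "n_markers_in_block": len(c.block_markers),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df["_pos"] = [int(s.split("-")[0]) for s in df["pos_span"]]
        df = df.sort_values(["gene", "chrom", "_pos"]).drop(columns="_pos")
    df.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
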