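"""Linkage-map and RIL genotype handling for interval-mapping scans.

The coordinate system for every genome scan in this package is a genetic
map: ordered markers with a chromosome label and a position in
centimorgans.  Genotypes come from a biparental recombinant-inbred-line
(RIL) population and therefore fall into two homozygous parental classes,
coded internally as 0 (A parent) and 1 (B parent); missing calls are NaN.
With this coding an estimated QTL effect is the full difference between
the two homozygote classes.

Expected recombination between RIL genotypes uses the Haldane map function
expanded for repeated selfing (Haldane–Waddington):

    r(d) = (1 - exp(-2 d / 100)) / 2,      R = 2 r / (1 + 2 r)

so R increases monotonically to 1/2 as d grows.  Conditional QTL-genotype scores at arbitrary map
positions are computed from the nearest informative flanking marker on each
side via the two-state Markov chain with transition probability R between
adjacent loci — the standard interval-mapping regressor for near-fully
informative RIL data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("altqtl")

MISSING_CODES = {"-", "NA", "", "."}
CODE_A = "A"
CODE_B = "B"


class MapError(ValueError):
    """Raised for invalid genetic maps or genotype tables."""


# ---------------------------------------------------------------------------
# map function


def ril_recombination_fraction(d):
    """Expected recombinant fraction between selfed-RIL genotypes at ``d`` cM.

    Haldane per-meiosis fraction r = (1 - exp(-2d/100)) / 2 expanded with the
    Haldane–Waddington formula R = 2r / (1 + 2r).  Monotone in ``d``,
    approaching 1/2 (r -> 1/2) at large distance.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    R = 2.0 * r / (1.0 + 2.0 * r)
    return R if R.ndim else float(R)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers with chromosome labels and cM positions.

    ``table`` has columns ``marker``, ``chromosome``, ``position_cM`` and is
    sorted by (chromosome, position); chromosome order follows first
    appearance in the input.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"marker", "chromosome", "position_cM"}
        if not required.issubset(t.columns):
            raise MapError(f"map table must have columns {sorted(required)}")
        dup = t["marker"][t["marker"].duplicated()]
        if len(dup):
            raise MapError(f"duplicate marker id(s): {sorted(set(dup))}")
        pos = pd.to_numeric(t["position_cM"], errors="coerce")
        if pos.isna().any():
            bad = t.loc[pos.isna(), "marker"].tolist()
            raise MapError(f"non-numeric position for marker(s): {bad}")
        if (pos < 0).any():
            bad = t.loc[pos < 0, "marker"].tolist()
            raise MapError(f"negative position for marker(s): {bad}")
        chrom_order = list(dict.fromkeys(t["chromosome"].astype(str)))
        t = t.assign(
            chromosome=t["chromosome"].astype(str), position_cM=pos.astype(float)
        )
        key = t["chromosome"].map({c: i for i, c in enumerate(chrom_order)})
        sorted_t = t.iloc[np.lexsort((t["position_cM"].to_numpy(), key.to_numpy()))]
        if not sorted_t.index.equals(t.index):
            logger.info("genetic map was not sorted; sorting by (chromosome, position)")
        object.__setattr__(self, "table", sorted_t.reset_index(drop=True))

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def chromosome_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == str(chrom)]

    def positions(self, chrom: str) -> np.ndarray:
        return self.chromosome_table(chrom)["position_cM"].to_numpy()

    def flanking_markers(self, chrom: str, pos: float) -> tuple[str, str]:
        """Nearest marker at-or-left and at-or-right of ``pos``."""
        t = self.chromosome_table(chrom)
        p = t["position_cM"].to_numpy()
        li = int(np.searchsorted(p, pos, side="right")) - 1
        ri = int(np.searchsorted(p, pos, side="left"))
        li = max(li, 0)
        ri = min(ri, len(p) - 1)
        return t["marker"].iloc[li], t["marker"].iloc[ri]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Line x marker parental-origin codes, 0 = A parent, 1 = B parent, NaN missing.

    ``data`` is indexed by line id with one column per marker, in map order.
    """

    data: pd.DataFrame

    @property
    def line_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_lines(self) -> int:
        return len(self.data)

    def values_for(self, gmap: GeneticMap, chrom: str) -> np.ndarray:
        cols = gmap.chromosome_table(chrom)["marker"].tolist()
        return self.data[cols].to_numpy(dtype=float)

    @classmethod
    def from_codes(cls, codes: pd.DataFrame, gmap: GeneticMap) -> "GenotypeMatrix":
        """Validate a table of A/B/- symbols against the map and encode 0/1/NaN.

        Heterozygous calls ('H') are treated as missing (two-class RIL model)
        with a logged count; any other symbol is an error.  Columns are
        reordered to map order.
        """
        unknown = [c for c in codes.columns if c not in set(gmap.markers)]
        if unknown:
            raise MapError(f"unknown marker column(s): {unknown}")
        missing_cols = [m for m in gmap.markers if m not in codes.columns]
        if missing_cols:
            raise MapError(f"genotype table lacks map marker(s): {missing_cols}")
        codes = codes[gmap.markers]
        arr = codes.to_numpy(dtype=object)
        out = np.full(arr.shape, np.nan)
        n_het = 0
        for sym, val in ((CODE_A, 0.0), (CODE_B, 1.0)):
            out[arr == sym] = val
        het_mask = arr == "H"
        n_het = int(het_mask.sum())
        known = (
            np.isin(arr, [CODE_A, CODE_B, "H"])
            | np.isin(arr, list(MISSING_CODES))
            | pd.isna(arr.astype(object))
        )
        if not known.all():
            bad = sorted({str(s) for s in arr[~known]})
            raise MapError(f"genotype symbol(s) outside alphabet A/B/-: {bad}")
        if n_het:
            logger.info("treated %d heterozygous calls as missing", n_het)
        data = pd.DataFrame(out, index=codes.index.astype(str), columns=codes.columns)
        miss_frac = data.isna().mean(axis=1)
        for line, frac in miss_frac[miss_frac > 0].items():
            logger.debug("line %s: %.1f%% missing genotypes", line, 100 * frac)
        logger.info(
            "loaded %d lines x %d markers (%.2f%% missing)",
            data.shape[0], data.shape[1], 100 * float(data.isna().mean().mean()),
        )
        return cls(data)

    def to_codes(self) -> pd.DataFrame:
        arr = self.data.to_numpy()
        out = np.full(arr.shape, "-", dtype=object)
        out[arr == 0.0] = CODE_A
        out[arr == 1.0] = CODE_B
        return pd.DataFrame(out, index=self.data.index, columns=self.data.columns)


@dataclass(frozen=True)
class ScanGrid:
    """Ordered genome-scan evaluation positions: every marker plus fill-ins.

    ``table`` has columns ``chromosome``, ``position_cM``; consecutive
    within-chromosome positions differ by at most ``step``.
    """

    table: pd.DataFrame
    step: float

    @property
    def n_positions(self) -> int:
        return len(self.table)

    def positions(self, chrom: str) -> np.ndarray:
        t = self.table
        return t.loc[t["chromosome"] == str(chrom), "position_cM"].to_numpy()


@dataclass(frozen=True)
class QTLGenotypeScores:
    """Conditional P(B-parent genotype) per line at every scan-grid position."""

    values: np.ndarray  # n_lines x n_positions, in grid order
    grid: ScanGrid
    line_ids: list[str] = field(default_factory=list)

    def column(self, index: int) -> np.ndarray:
        return self.values[:, index]


# ---------------------------------------------------------------------------
# file I/O (delimited text)


def load_genetic_map(path) -> GeneticMap:
    """Read a delimited map file with columns marker, chromosome, position_cM."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"marker": str})
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want in ("marker", "chromosome", "position_cm"):
        if want not in cols:
            raise MapError(f"map file missing column '{want}'")
        rename[cols[want]] = "position_cM" if want == "position_cm" else want
    return GeneticMap(df.rename(columns=rename)[["marker", "chromosome", "position_cM"]])


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, index=False)


def load_genotypes(path, gmap: GeneticMap) -> GenotypeMatrix:
    """Read a delimited genotype file: first column line id, then A/B/- per marker."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df = df.set_index(df.columns[0])
    return GenotypeMatrix.from_codes(df, gmap)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    geno.to_codes().rename_axis("line").to_csv(path)


# ---------------------------------------------------------------------------
# scan grid and conditional genotype scores


def build_scan_grid(gmap: GeneticMap, step: float = 2.0) -> ScanGrid:
    """Marker positions plus interpolated points so within-chromosome gaps <= step."""
    if step <= 0:
        raise ValueError("grid step must be > 0")
    rows = []
    for chrom in gmap.chromosomes:
        pos = np.unique(gmap.positions(chrom))
        pts = []
        for left, right in zip(pos[:-1], pos[1:]):
            pts.append(left)
            fill = left + step * np.arange(1, int(np.ceil((right - left) / step)))
            pts.extend(p for p in fill if p < right - 1e-9)
        pts.append(pos[-1])
        rows.extend((chrom, float(p)) for p in pts)
    table = pd.DataFrame(rows, columns=["chromosome", "position_cM"])
    return ScanGrid(table=table, step=float(step))


def _flank_weights(g_left, R_left, g_right, R_right):
    """P(query = B) given flanking genotypes and recombination fractions."""
    pB_L = g_left * (1 - R_left) + (1 - g_left) * R_left
    pA_L = 1.0 - pB_L
    pB_R = g_right * (1 - R_right) + (1 - g_right) * R_right
    pA_R = 1.0 - pB_R
    w1 = pB_L * pB_R
    w0 = pA_L * pA_R
    return w1 / (w0 + w1)


def genotype_probabilities(
    geno: GenotypeMatrix, gmap: GeneticMap, grid: ScanGrid
) -> QTLGenotypeScores:
    """Conditional QTL-genotype scores x = P(B | flanking markers) on the grid.

    Conditioning uses the nearest non-missing marker on each side via the
    two-state chain with transition probability R between loci; one informative
    side conditions on that side alone; a chromosome with no informative
    marker for a line yields x = 0.5.
    """
    blocks = []
    for chrom in gmap.chromosomes:
        p = gmap.positions(chrom)
        G = geno.values_for(gmap, chrom)
        q = grid.positions(chrom)
        if len(q) == 0:
            continue
        if not np.isnan(G).any():
            li = np.clip(np.searchsorted(p, q, side="right") - 1, 0, len(p) - 1)
            ri = np.clip(np.searchsorted(p, q, side="left"), 0, len(p) - 1)
            RL = ril_recombination_fraction(q - p[li])
            RR = ril_recombination_fraction(p[ri] - q)
            x = _flank_weights(G[:, li], RL[None, :], G[:, ri], RR[None, :])
        else:
            x = np.empty((G.shape[0], len(q)))
            for i in range(G.shape[0]):
                x[i] = _scores_one_line(G[i], p, q)
        blocks.append(x)
    values = np.concatenate(blocks, axis=1)
    return QTLGenotypeScores(values=values, grid=grid, line_ids=geno.line_ids)


def _scores_one_line(g: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(g)
    if not obs.any():
        return np.full(len(q), 0.5)
    po, go = p[obs], g[obs]
    li = np.searchsorted(po, q, side="right") - 1
    ri = np.searchsorted(po, q, side="left")
    out = np.empty(len(q))
    for j in range(len(q)):
        has_l, has_r = li[j] >= 0, ri[j] < len(po)
        if has_l and has_r:
            RL = ril_recombination_fraction(q[j] - po[li[j]])
            RR = ril_recombination_fraction(po[ri[j]] - q[j])
            out[j] = _flank_weights(go[li[j]], RL, go[ri[j]], RR)
        elif has_l:
            R = ril_recombination_fraction(q[j] - po[li[j]])
            out[j] = go[li[j]] * (1 - R) + (1 - go[li[j]]) * R
        else:
            R = ril_recombination_fraction(po[ri[j]] - q[j])
            out[j] = go[ri[j]] * (1 - R) + (1 - go[ri[j]]) * R
    return out
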