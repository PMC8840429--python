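"""Sliding-window genotype calling, breakpoint detection and recombination bins.

The window caller slides a 50-site window in 1-site steps along each
line's SNP calls; a window is called homozygous for a parent when strictly
more than 2/3 of its allele evidence supports that parent (heterozygous
site calls contribute half a count to each side), heterozygous otherwise,
and missing when fewer than ``min_informative`` sites carry a call.

Window calls are smoothed back onto sites (each site takes the call of the
window centred on it) and segmented into maximal runs.  Runs of
heterozygous calls shorter than one window length flanked by opposite
homozygous runs are the unavoidable transition zone the majority rule
produces around a clean crossover; they are collapsed to a single
breakpoint at the zone midpoint.  Remaining breakpoints sit at the
midpoint between the last site of one run and the first site of the next
(ties resolved toward the lower coordinate).

The population-wide bin matrix partitions every chromosome into 50 kb grid
intervals, assigns each interval the genotype covering the majority of its
span per line, and merges adjacent intervals whose genotype vectors agree
across all lines — a bin is an interval without a recombination breakpoint
in any line.  Bins are then screened for segregation distortion with a
chi-square test against the pedigree expectation (AA:BB = 7:1 for BC2 in
the complete-inbreeding limit).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import codes
from .panel import SNPCallMatrix

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeTrack",
    "GenotypeTracks",
    "BinMatrix",
    "call_windows",
    "segment_genotypes",
    "call_tracks",
    "build_bins",
    "filter_distortion",
    "composition_report",
]


def call_windows(
    site_calls: np.ndarray,
    window: int = 50,
    step: int = 1,
    majority: float = 2.0 / 3.0,
    min_informative: int = 10,
    het_half: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window genotype calls along one line and chromosome.

    Returns ``(calls, starts)`` where ``starts`` are the window start site
    indices.  Counting is done in integer half-units so the strict
    ``> majority`` comparison is exact at the 2/3 boundary.  A chromosome
    with fewer sites than ``window`` yields a single window over all sites
    (logged).  ``het_half=False`` excludes heterozygous site calls instead.
    """
    g = np.asarray(site_calls)
    n = len(g)
    if n == 0:
        return np.empty(0, np.int8), np.empty(0, np.intp)
    if n < window:
        log.debug("chromosome with %d < %d sites; single window", n, window)
        window = n
    is_a = (g == codes.AA).astype(np.int64)
    is_b = (g == codes.BB).astype(np.int64)
    is_h = (g == codes.HET).astype(np.int64) if het_half else np.zeros(n, np.int64)
    informative = (g != codes.MISSING).astype(np.int64)

    def winsum(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(x)])
        return c[window:] - c[:-window]

    starts = np.arange(0, n - window + 1, step)
    a2 = (2 * winsum(is_a) + winsum(is_h))[starts]  # evidence in half-units x2
    b2 = (2 * winsum(is_b) + winsum(is_h))[starts]
    n_inf = winsum(informative)[starts]
    tot = a2 + b2
    out = np.full(len(starts), codes.HET, dtype=np.int8)
    # strict majority: a2/tot > 2/3  <=>  3*a2 > 2*tot (exact in integers)
    if majority == 2.0 / 3.0:
        out[3 * a2 > 2 * tot] = codes.AA
        out[3 * b2 > 2 * tot] = codes.BB
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.where(tot > 0, a2 / np.maximum(tot, 1), 0.0)
            fb = np.where(tot > 0, b2 / np.maximum(tot, 1), 0.0)
        out[fa > majority] = codes.AA
        out[fb > majority] = codes.BB
    out[(n_inf < min_informative) | (tot == 0)] = codes.MISSING
    return out, starts


def _smooth_to_sites(window_calls: np.ndarray, n_sites: int, window: int) -> np.ndarray:
    """Assign each site the call of the window centred on it (clipped at ends)."""
    m = len(window_calls)
    if m == 0:
        return np.full(n_sites, codes.MISSING, np.int8)
    idx = np.clip(np.arange(n_sites) - window // 2, 0, m - 1)
    return window_calls[idx]


def _rle(x: np.ndarray) -> list[list]:
    """Run-length encode to mutable [start, stop, value] triples (stop exclusive)."""
    if len(x) == 0:
        return []
    cut = np.flatnonzero(np.diff(x)) + 1
    starts = np.concatenate([[0], cut])
    stops = np.concatenate([cut, [len(x)]])
    return [[int(s), int(e), int(x[s])] for s, e in zip(starts, stops)]


def _merge_equal(runs: list[list]) -> list[list]:
    out: list[list] = []
    for r in runs:
        if out and out[-1][2] == r[2]:
            out[-1][1] = r[1]
        else:
            out.append(list(r))
    return out


def segment_genotypes(
    window_calls: np.ndarray,
    positions: np.ndarray,
    window: int = 50,
    chrom_span: tuple[float, float] | None = None,
    collapse_het: int | None = None,
) -> tuple[list[tuple[float, float, int]], np.ndarray]:
    """Segment one line's window calls into a genotype track.

    Returns ``(runs, breakpoints)``: runs are half-open ``(start_bp,
    end_bp, code)`` spans tiling ``chrom_span`` and breakpoints are the bp
    positions between adjacent runs.  Missing stretches inherit the
    flanking run when both flanks agree; heterozygous runs shorter than
    ``collapse_het`` sites (default: one window) between homozygous flanks
    are collapsed as crossover transition zones.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if collapse_het is None:
        collapse_het = window
    if chrom_span is None:
        chrom_span = (0.0, float(positions[-1]) if n else 0.0)
    site_calls = _smooth_to_sites(np.asarray(window_calls), n, window)
    runs = _rle(site_calls)

    # missing runs inherit agreeing flanks
    for i, r in enumerate(runs):
        if r[2] == codes.MISSING and 0 < i < len(runs) - 1 and runs[i - 1][2] == runs[i + 1][2]:
            r[2] = runs[i - 1][2]
    runs = _merge_equal(runs)

    # collapse short heterozygous transition zones
    changed = True
    while changed:
        changed = False
        for i, r in enumerate(runs):
            if r[2] != codes.HET or r[1] - r[0] >= collapse_het:
                continue
            left = runs[i - 1][2] if i > 0 else None
            right = runs[i + 1][2] if i < len(runs) - 1 else None
            homs = (codes.AA, codes.BB)
            if left in homs and right in homs:
                if left == right:
                    r[2] = left
                else:
                    # crossover transition zone: split it at its central site
                    # pair so the breakpoint midpoint falls between the two
                    # sites flanking the inferred junction (ties toward the
                    # lower coordinate)
                    centre = (r[0] + r[1]) // 2
                    runs[i - 1][1] = centre
                    runs[i + 1][0] = centre
                    runs.pop(i)
                changed = True
                break
            if left is None and right in homs:
                r[2] = right
                changed = True
                break
            if right is None and left in homs:
                r[2] = left
                changed = True
                break
        runs = _merge_equal(runs)

    if not runs or n == 0:
        return [(chrom_span[0], chrom_span[1], codes.MISSING)], np.empty(0)

    breakpoints = []
    for left, right in zip(runs[:-1], runs[1:]):
        lo = positions[left[1] - 1]
        hi = positions[right[0]]
        breakpoints.append(math.floor((lo + hi) / 2))
    bounds = [chrom_span[0]] + breakpoints + [chrom_span[1]]
    spans = [
        (float(bounds[i]), float(bounds[i + 1]), runs[i][2]) for i in range(len(runs))
    ]
    return spans, np.asarray(breakpoints, dtype=float)


#: per-line track: chrom -> list of (start_bp, end_bp, code) half-open runs
GenotypeTrack = dict


@dataclass
class GenotypeTracks:
    """All lines' genotype tracks over a common set of chromosomes."""

    tracks: list[GenotypeTrack]
    chrom_spans: dict
    line_names: list[str]

    @property
    def chroms(self) -> list:
        return list(self.chrom_spans)

    def breakpoints(self, line: int, chrom) -> np.ndarray:
        runs = self.tracks[line][chrom]
        return np.array([r[0] for r in runs[1:]])

    def breakpoint_counts(self) -> np.ndarray:
        """Per-line total breakpoints (= runs - 1 summed over chromosomes)."""
        return np.array(
            [sum(len(t[c]) - 1 for c in self.chrom_spans) for t in self.tracks]
        )


def call_tracks(
    panel: SNPCallMatrix,
    window: int = 50,
    step: int = 1,
    majority: float = 2.0 / 3.0,
    min_informative: int = 10,
    chrom_spans: dict | None = None,
    het_half: bool = True,
) -> GenotypeTracks:
    """Window-call and segment every line on every chromosome."""
    if chrom_spans is None:
        chrom_spans = {
            c: (0.0, float(panel.sites["pos"].iloc[panel.chrom_slice(c)].max()))
            for c in panel.chroms
        }
    tracks: list[GenotypeTrack] = []
    chrom_idx = {c: panel.chrom_slice(c) for c in panel.chroms}
    for i in range(panel.n_lines):
        t: GenotypeTrack = {}
        for c in panel.chroms:
            idx = chrom_idx[c]
            pos = panel.sites["pos"].to_numpy()[idx]
            w, _ = call_windows(
                panel.calls[i, idx], window, step, majority, min_informative, het_half
            )
            t[c], _ = segment_genotypes(w, pos, min(window, max(len(idx), 1)), chrom_spans[c])
        tracks.append(t)
    return GenotypeTracks(tracks, dict(chrom_spans), list(panel.samples))


@dataclass
class BinMatrix:
    """Recombination bins x lines genotype matrix.

    Bins are half-open [start, end) bp intervals tiling the grid-covered
    part of each chromosome; adjacent bins differ in at least one line.
    """

    bins: pd.DataFrame  # chrom, start, end, n_snps
    genotypes: np.ndarray  # int8 (n_bins, n_lines)
    samples: list[str]
    distortion_p: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_lines(self) -> int:
        return len(self.samples)

    def chrom_rows(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())

    def transitions_per_line(self) -> np.ndarray:
        """Breakpoints recounted from bin-genotype transitions (per line)."""
        out = np.zeros(self.n_lines, dtype=int)
        for c in pd.unique(self.bins["chrom"]):
            g = self.genotypes[self.chrom_rows(c)]
            for i in range(self.n_lines):
                col = g[:, i]
                col = col[col != codes.MISSING]
                if len(col) > 1:
                    out[i] += int(np.sum(col[1:] != col[:-1]))
        return out


def build_bins(
    tracks: GenotypeTracks,
    site_positions: dict | None = None,
    grid: int = 50_000,
) -> BinMatrix:
    """Grid the genome at ``grid`` bp, genotype each interval per line by
    majority span (exact ties -> missing), and merge adjacent intervals with
    identical genotype vectors across all lines.

    Intervals containing no retained SNP are absorbed into their left
    neighbour (right at a chromosome start) so every bin keeps n_snps >= 1.
    """
    n_lines = len(tracks.tracks)
    all_rows = []
    all_cols = []
    cat = [codes.AA, codes.HET, codes.BB, codes.MISSING]
    cat_pos = {c: k for k, c in enumerate(cat)}
    for chrom, (lo, hi) in tracks.chrom_spans.items():
        n_int = max(int(math.ceil((hi - lo) / grid)), 1)
        geno = np.full((n_int, n_lines), codes.MISSING, dtype=np.int8)
        for li, track in enumerate(tracks.tracks):
            occ = np.zeros((n_int, 4))
            for s, e, code in track[chrom]:
                i0 = int((s - lo) // grid)
                i1 = min(int(math.ceil((e - lo) / grid)), n_int)
                for g_i in range(max(i0, 0), i1):
                    a = max(s, lo + g_i * grid)
                    b = min(e, lo + (g_i + 1) * grid)
                    if b > a:
                        occ[g_i, cat_pos[code]] += b - a
            best = np.argmax(occ, axis=1)
            top = occ[np.arange(n_int), best]
            tie = (occ >= top[:, None] - 1e-9).sum(axis=1) > 1
            g_col = np.array([cat[b] for b in best], dtype=np.int8)
            g_col[tie] = codes.MISSING
            g_col[top <= 0] = codes.MISSING
            geno[:, li] = g_col
        # merge equal adjacent genotype vectors
        if n_int > 1:
            diff = np.any(geno[1:] != geno[:-1], axis=1)
            group = np.concatenate([[0], np.cumsum(diff)])
        else:
            group = np.zeros(1, dtype=int)
        n_groups = group[-1] + 1
        starts = np.array([lo + np.flatnonzero(group == g)[0] * grid for g in range(n_groups)])
        ends = np.array(
            [min(lo + (np.flatnonzero(group == g)[-1] + 1) * grid, hi) for g in range(n_groups)]
        )
        gmat = geno[[np.flatnonzero(group == g)[0] for g in range(n_groups)]]
        if site_positions is not None and chrom in site_positions:
            pos = np.asarray(site_positions[chrom])
            n_snps = np.searchsorted(pos, ends, side="right") - np.searchsorted(
                pos, starts, side="right"
            )
        else:
            n_snps = np.ones(n_groups, dtype=int)
        # absorb SNP-less bins into a neighbour (left; right at a chrom start)
        keep = n_snps > 0
        if keep.any() and not keep.all():
            m_starts: list[float] = []
            m_ends: list[float] = []
            m_rows: list[np.ndarray] = []
            m_snps: list[int] = []
            pending_start: float | None = None
            for g in range(n_groups):
                if keep[g]:
                    m_starts.append(starts[g] if pending_start is None else pending_start)
                    m_ends.append(ends[g])
                    m_rows.append(gmat[g])
                    m_snps.append(int(n_snps[g]))
                    pending_start = None
                elif m_ends:
                    m_ends[-1] = ends[g]
                elif pending_start is None:
                    pending_start = starts[g]
            starts = np.asarray(m_starts)
            ends = np.asarray(m_ends)
            gmat = np.vstack(m_rows)
            n_snps = np.asarray(m_snps)
        all_rows.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "n_snps": n_snps})
        )
        all_cols.append(gmat)
    bins = pd.concat(all_rows, ignore_index=True)
    genotypes = np.vstack(all_cols)
    return BinMatrix(bins, genotypes, list(tracks.line_names))


def filter_distortion(
    bm: BinMatrix, alpha: float = 0.005, expected_ratio: tuple[float, float] = (7.0, 1.0)
) -> BinMatrix:
    """Chi-square goodness-of-fit of homozygote counts against the pedigree
    ratio (df = 1); bins with p < alpha are removed.  Bins with fewer than
    two homozygous calls are retained with missing p (logged)."""
    n_aa = (bm.genotypes == codes.AA).sum(axis=1)
    n_bb = (bm.genotypes == codes.BB).sum(axis=1)
    tot = n_aa + n_bb
    ra, rb = expected_ratio
    frac_a = ra / (ra + rb)
    p = np.full(bm.n_bins, np.nan)
    ok = tot >= 2
    if ok.any():
        ea = tot[ok] * frac_a
        eb = tot[ok] * (1 - frac_a)
        chi2 = (n_aa[ok] - ea) ** 2 / ea + (n_bb[ok] - eb) ** 2 / eb
        p[ok] = stats.chi2.sf(chi2, df=1)
    n_low = int((~ok).sum())
    if n_low:
        log.info("filter_distortion: %d bins with < 2 homozygous calls retained untested", n_low)
    keep = ~(p < alpha)  # NaN p compares False -> retained
    log.info("filter_distortion: removed %d of %d bins at p < %g", int((~keep).sum()), bm.n_bins, alpha)
    out = replace(
        bm,
        bins=bm.bins.loc[keep].reset_index(drop=True),
        genotypes=bm.genotypes[keep],
        distortion_p=p[keep],
    )
    return out


def composition_report(bm: BinMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line and per-chromosome parental genome composition.

    Fractions of Af (AA) and Ws (BB) among homozygous bins, unweighted by
    bin span, plus the heterozygous fraction among called bins.  The
    per-chromosome table averages the per-line fractions.
    """
    if bm.n_bins == 0:
        raise ValueError("empty BinMatrix")
    rows = []
    for i, name in enumerate(bm.samples):
        col = bm.genotypes[:, i]
        n_aa = int(np.sum(col == codes.AA))
        n_bb = int(np.sum(col == codes.BB))
        n_h = int(np.sum(col == codes.HET))
        hom = n_aa + n_bb
        rows.append(
            {
                "line": name,
                "n_bins_af": n_aa,
                "n_bins_ws": n_bb,
                "n_bins_het": n_h,
                "frac_af": n_aa / hom if hom else np.nan,
                "frac_ws": n_bb / hom if hom else np.nan,
                "frac_het": n_h / (hom + n_h) if hom + n_h else np.nan,
            }
        )
    per_line = pd.DataFrame(rows)
    crows = []
    for c in pd.unique(bm.bins["chrom"]):
        g = bm.genotypes[bm.chrom_rows(c)]
        n_aa = (g == codes.AA).sum(axis=0)
        n_bb = (g == codes.BB).sum(axis=0)
        hom = n_aa + n_bb
        with np.errstate(invalid="ignore"):
            frac_ws = np.where(hom > 0, n_bb / np.maximum(hom, 1), np.nan)
        crows.append({"chrom": c, "mean_frac_ws": float(np.nanmean(frac_ws))})
    return per_line, pd.DataFrame(crows)
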