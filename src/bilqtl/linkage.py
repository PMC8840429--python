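"""Recombination fractions, Kosambi distances and physically anchored maps.

Between adjacent bins the observed recombinant fraction R counts only
lines homozygous at both bins; because the lines are (nearly) fully
inbred, repeated meioses inflate R relative to the single-meiosis
recombination fraction r.  The selfed-RIL relation r = R / (2 - 2R)
undoes that expansion before the Kosambi map function
d = 25 * ln((1 + 2r) / (1 - 2r)) cM converts r to additive distance.
Linkage groups are anchored to physical order (no de novo ordering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes
from .binning import BinMatrix

log = logging.getLogger(__name__)

__all__ = [
    "LinkageMap",
    "estimate_rf",
    "kosambi_cM",
    "kosambi_r",
    "haldane_cM",
    "haldane_r",
    "ril_self_correction",
    "assemble_map",
    "summarize_map",
    "summarize_counts",
    "write_map_tsv",
]

R_CAP = 0.4999


def bil_observed_R(r: float, n_backcross: int = 2, n_selfs: int = 6) -> float:
    """Exact two-locus observed recombinant fraction for the BIL pedigree.

    Propagates the joint two-locus diplotype distribution through the
    pedigree (F1, ``n_backcross`` backcrosses to the AA parent, then
    ``n_selfs`` selfing generations) for a single-meiosis recombination
    fraction ``r`` and returns the probability that the genotypes at the
    two loci differ among the final lines.  For a selfed RIL this recovers
    the Haldane-Waddington R = 2r/(1+2r); for BC2S6 the backcrosses erase
    most junction accumulation and R ~ 1.05 r at small r.
    """
    from collections import defaultdict

    def gametes(plant, out, w):
        h1, h2 = plant
        out[h1] += w * (1 - r) / 2
        out[h2] += w * (1 - r) / 2
        out[(h1[0], h2[1])] += w * r / 2
        out[(h2[0], h1[1])] += w * r / 2

    def gamete_dist(dist):
        out = defaultdict(float)
        for plant, p in dist.items():
            gametes(plant, out, p)
        return out

    def cross(gm, gf):
        out = defaultdict(float)
        for hm, pm in gm.items():
            for hf, pf in gf.items():
                out[(hm, hf)] += pm * pf
        return out

    A, B = (0, 0), (1, 1)
    dist = {(B, A): 1.0}
    af = {(A, A): 1.0}
    for _ in range(n_backcross):
        dist = cross(gamete_dist(dist), gamete_dist(af))
    for _ in range(n_selfs):
        out = defaultdict(float)
        for plant, p in dist.items():
            g = defaultdict(float)
            gametes(plant, g, 1.0)
            for h1, p1 in g.items():
                for h2, p2 in g.items():
                    out[(h1, h2)] += p * p1 * p2
        dist = out
    return float(
        sum(p for (h1, h2), p in dist.items() if h1[0] + h2[0] != h1[1] + h2[1])
    )


_BIL_TABLE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def bil_correction(R: float, n_backcross: int = 2, n_selfs: int = 6) -> float:
    """Meiotic r from the observed R by inverting :func:`bil_observed_R`.

    Uses a cached monotone interpolation table; R beyond the pedigree's
    two-locus saturation value maps to the 0.4999 cap.
    """
    if np.isnan(R):
        return np.nan
    key = (n_backcross, n_selfs)
    if key not in _BIL_TABLE:
        r_grid = np.linspace(0.0, R_CAP, 201)
        R_grid = np.array([bil_observed_R(r, n_backcross, n_selfs) for r in r_grid])
        _BIL_TABLE[key] = (R_grid, r_grid)
    R_grid, r_grid = _BIL_TABLE[key]
    if R >= R_grid[-1]:
        return R_CAP
    return float(np.interp(R, R_grid, r_grid))


def estimate_rf(
    g1: np.ndarray, g2: np.ndarray, correction: str = "bil"
) -> tuple[float, float, int]:
    """Observed recombinant fraction R and meiotic r between two bins.

    Only lines homozygous at both bins are informative: equal homozygotes
    are parental, opposite homozygotes recombinant.  Returns
    ``(R, r, n_informative)``; with zero informative lines both fractions
    are NaN.  ``correction`` maps R to the single-meiosis r: ``"bil"``
    (exact BC2S6 two-locus inversion, default), ``"ril-self"``
    (r = R/(2-2R)) or ``"none"``; r is capped at 0.4999.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    hom = np.isin(g1, (codes.AA, codes.BB)) & np.isin(g2, (codes.AA, codes.BB))
    n = int(hom.sum())
    if n == 0:
        return np.nan, np.nan, 0
    rec = int(np.sum(g1[hom] != g2[hom]))
    R = rec / n
    return R, apply_correction(R, correction), n


def apply_correction(R: float, correction: str) -> float:
    if correction == "bil":
        return bil_correction(R)
    if correction == "ril-self":
        return ril_self_correction(R)
    if correction == "none":
        return min(R, R_CAP)
    raise ValueError("correction must be 'bil', 'ril-self' or 'none'")


def ril_self_correction(R: float) -> float:
    """Selfed-RIL inversion r = R / (2 - 2R), capped below 0.5."""
    if np.isnan(R):
        return np.nan
    return min(R / (2.0 - 2.0 * R) if R < 1 else np.inf, R_CAP)


def kosambi_cM(r) -> np.ndarray | float:
    """Kosambi map function d = 25 * ln((1 + 2r) / (1 - 2r)) in cM."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr >= 0.5) or np.any(r_arr < 0):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r_arr) / (1 - 2 * r_arr))
    return float(d) if np.isscalar(r) else d


def kosambi_r(d_cM) -> np.ndarray | float:
    """Inverse Kosambi: r = tanh(2d/100) / 2."""
    return np.tanh(2 * np.asarray(d_cM, dtype=float) / 100.0) / 2.0


def haldane_cM(r) -> np.ndarray | float:
    """Haldane map function d = -50 * ln(1 - 2r) in cM."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr >= 0.5) or np.any(r_arr < 0):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = -50.0 * np.log(1 - 2 * r_arr)
    return float(d) if np.isscalar(r) else d


def haldane_r(d_cM) -> np.ndarray | float:
    """Inverse Haldane: r = (1 - exp(-2d/100)) / 2."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0)) / 2.0


@dataclass
class LinkageMap:
    """Ordered bins with cumulative cM positions per chromosome."""

    chroms: list
    bin_rows: dict  # chrom -> row indices into the BinMatrix
    pos_cM: dict  # chrom -> cumulative positions (cM)
    gaps: dict  # chrom -> adjacent-gap list (len n_bins - 1)
    n_bridged: int = 0
    n_capped: int = 0

    def length(self, chrom) -> float:
        p = self.pos_cM[chrom]
        return float(p[-1]) if len(p) else 0.0

    @property
    def total_length(self) -> float:
        return float(sum(self.length(c) for c in self.chroms))


def assemble_map(bm: BinMatrix, correction: str = "bil") -> LinkageMap:
    """Cumulative Kosambi positions along the physical bin order.

    ``correction`` is ``"bil"`` (exact pedigree inversion, default),
    ``"ril-self"`` (r = R/(2-2R)) or ``"none"`` (r = R).  Adjacent pairs
    with no informative line are bridged: the distance between the
    nearest informative flanking bins is split equally over the
    intervening gaps (logged).
    """
    if correction not in ("bil", "ril-self", "none"):
        raise ValueError("correction must be 'bil', 'ril-self' or 'none'")
    chroms = list(pd.unique(bm.bins["chrom"]))
    bin_rows, pos_map, gap_map = {}, {}, {}
    n_bridged = n_capped = 0
    for c in chroms:
        rows = bm.chrom_rows(c)
        bin_rows[c] = rows
        k = len(rows)
        if k < 2:
            log.info("chromosome %s has %d bin(s); zero-length group", c, k)
            pos_map[c] = np.zeros(k)
            gap_map[c] = np.empty(0)
            continue
        gaps = np.full(k - 1, np.nan)
        for j in range(k - 1):
            R, r, n = estimate_rf(
                bm.genotypes[rows[j]], bm.genotypes[rows[j + 1]], correction
            )
            if n == 0:
                continue
            if R >= 1:
                n_capped += 1
            gaps[j] = kosambi_cM(r)
        # bridge gaps with no informative pair
        nan_idx = np.flatnonzero(np.isnan(gaps))
        if len(nan_idx):
            n_bridged += len(nan_idx)
            for block in np.split(nan_idx, np.flatnonzero(np.diff(nan_idx) > 1) + 1):
                lo_bin, hi_bin = block[0], block[-1] + 1
                R, r, n = estimate_rf(
                    bm.genotypes[rows[lo_bin]], bm.genotypes[rows[hi_bin]], correction
                )
                d = 0.0 if n == 0 else kosambi_cM(r)
                gaps[block] = d / len(block)
            log.info("chromosome %s: %d uninformative gaps bridged", c, len(nan_idx))
        pos_map[c] = np.concatenate([[0.0], np.cumsum(gaps)])
        gap_map[c] = gaps
    return LinkageMap(chroms, bin_rows, pos_map, gap_map, n_bridged, n_capped)


def summarize_counts(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Map summary from per-chromosome totals.

    ``per_chrom`` needs columns ``chrom``, ``n_snps``, ``n_bins`` and
    ``length_cM`` (``max_gap_cM`` optional).  Mean inter-bin distance is
    length / n_bins — the convention that reproduces published per-
    chromosome values — and the Total row carries the genome-wide means,
    including mean SNPs per bin = total SNPs / total bins.
    """
    df = per_chrom.copy()
    df["mean_interbin_cM"] = df["length_cM"] / df["n_bins"]
    total = {
        "chrom": "Total",
        "n_snps": df["n_snps"].sum(),
        "n_bins": df["n_bins"].sum(),
        "length_cM": df["length_cM"].sum(),
        "mean_interbin_cM": df["length_cM"].sum() / df["n_bins"].sum(),
    }
    if "max_gap_cM" in df.columns:
        total["max_gap_cM"] = df["max_gap_cM"].max()
    out = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    out.attrs["mean_snps_per_bin"] = float(df["n_snps"].sum() / df["n_bins"].sum())
    return out


def summarize_map(lm: LinkageMap, bm: BinMatrix) -> pd.DataFrame:
    """Per-chromosome and total map characteristics (SNPs, bins, length,
    mean inter-bin distance, max gap)."""
    rows = []
    for c in lm.chroms:
        idx = lm.bin_rows[c]
        gaps = lm.gaps[c]
        rows.append(
            {
                "chrom": c,
                "n_snps": int(bm.bins["n_snps"].iloc[idx].sum()),
                "n_bins": len(idx),
                "length_cM": lm.length(c),
                "max_gap_cM": float(gaps.max()) if len(gaps) else 0.0,
            }
        )
    return summarize_counts(pd.DataFrame(rows))


def write_map_tsv(lm: LinkageMap, bm: BinMatrix, path) -> None:
    """TSV map: chrom, bin id, start bp, end bp, cM position."""
    frames = []
    for c in lm.chroms:
        idx = lm.bin_rows[c]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "bin_id": idx,
                    "start": bm.bins["start"].iloc[idx].to_numpy(),
                    "end": bm.bins["end"].iloc[idx].to_numpy(),
                    "cM": lm.pos_cM[c],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
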