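"""Composite interval mapping (CIM) over the recombination-bin map.

The scan is a Haley-Knott regression: at every pseudo-position on a 1 cM
lattice the trait (on line means) is regressed on the expected additive
genotype score x-hat, conditioned on the flanking bin genotypes through
Haldane recombination fractions, plus background cofactor bins selected by
forward-backward stepwise regression — excluding cofactors within half a
scanning window (default 10 cM) of the test position.  The test statistic
is LOD = (n/2) * log10(RSS0 / RSS1); the genome-wide significance
threshold is the (1 - alpha) quantile of the maximum LOD over permutations
of the trait across lines (cofactors re-selected per permutation).  A QTL
is a supra-threshold peak; its interval is the 1.5-LOD support region, its
additive effect the regression coefficient on x-hat (half the difference
between homozygote means, positive when the recurrent Af allele increases
the trait) and its PVE = 1 - 10^(-2*LOD/n), which in this regression
formulation equals the partial R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codes
from .binning import BinMatrix
from .linkage import LinkageMap, haldane_r

log = logging.getLogger(__name__)

__all__ = [
    "ScanGrid",
    "build_scan_grid",
    "bin_scores",
    "candidate_bins",
    "select_cofactors",
    "cim_scan",
    "permutation_threshold",
    "summarize_qtl",
    "CIMScanModel",
    "CIMScanResults",
]


@dataclass
class ScanGrid:
    """Pseudo-positions on a cM lattice with expected additive scores.

    ``X`` holds E[x | flanking bin genotypes] per line x position under the
    two-genotype inbred model; x-hat is exactly +/-1 at the position of a
    homozygous bin of that line.
    """

    chroms: list
    chrom_of: np.ndarray  # chromosome index per position
    pos_cM: np.ndarray
    X: np.ndarray  # (n_lines, n_positions)

    @property
    def n_positions(self) -> int:
        return len(self.pos_cM)

    @property
    def n_lines(self) -> int:
        return self.X.shape[0]

    def chrom_positions(self, ci: int) -> np.ndarray:
        return np.flatnonzero(self.chrom_of == ci)


def bin_scores(bm: BinMatrix, het: float = 0.0, missing: float = 0.0) -> np.ndarray:
    """Additive score per line x bin (AA +1, BB -1; het and missing
    default to 0, i.e. uninformative)."""
    x = codes.score(bm.genotypes.T)
    if het != 0.0:
        x = np.where(bm.genotypes.T == codes.HET, het, x)
    if missing != 0.0:
        x = np.where(bm.genotypes.T == codes.MISSING, missing, x)
    return x


def build_scan_grid(lm: LinkageMap, bm: BinMatrix, walk_step: float = 1.0) -> ScanGrid:
    """Lattice every ``walk_step`` cM (snapped to 0, plus the chromosome
    end) with per-line conditional scores from the flanking informative
    bins; single-flank conditioning at chromosome ends and across missing
    data; 0 where a line has no informative bin."""
    n_lines = bm.n_lines
    chrom_of, pos_all, x_cols = [], [], []
    for ci, c in enumerate(lm.chroms):
        rows = lm.bin_rows[c]
        bpos = lm.pos_cM[c]
        L = float(bpos[-1]) if len(bpos) else 0.0
        t = np.unique(np.concatenate([np.arange(0.0, L, walk_step), [L]]))
        X = np.zeros((n_lines, len(t)))
        g = bm.genotypes[rows]  # (k, n_lines)
        for li in range(n_lines):
            x = codes.score(g[:, li])
            info = np.abs(x) == 1.0
            if not info.any():
                continue
            bp = bpos[info]
            bx = x[info]
            iL = np.searchsorted(bp, t, side="right") - 1
            iR = np.searchsorted(bp, t, side="left")
            hasL = iL >= 0
            hasR = iR <= len(bp) - 1
            iLc = np.clip(iL, 0, len(bp) - 1)
            iRc = np.clip(iR, 0, len(bp) - 1)
            rL = haldane_r(t - bp[iLc])
            rR = haldane_r(bp[iRc] - t)
            pLp = np.where(bx[iLc] == 1.0, 1 - rL, rL)
            pRp = np.where(bx[iRc] == 1.0, 1 - rR, rR)
            wp = np.where(hasL, pLp, 1.0) * np.where(hasR, pRp, 1.0)
            wm = np.where(hasL, 1 - pLp, 1.0) * np.where(hasR, 1 - pRp, 1.0)
            xhat = (wp - wm) / (wp + wm)
            xhat[~(hasL | hasR)] = 0.0
            X[li] = xhat
        chrom_of.append(np.full(len(t), ci))
        pos_all.append(t)
        x_cols.append(X)
    return ScanGrid(
        list(lm.chroms),
        np.concatenate(chrom_of),
        np.concatenate(pos_all),
        np.hstack(x_cols),
    )


def candidate_bins(lm: LinkageMap, spacing_cM: float = 2.0) -> np.ndarray:
    """Thin bins to a minimum map spacing for the cofactor candidate set.

    Returns BinMatrix row indices.  ``spacing_cM = 0`` keeps every bin."""
    keep = []
    for c in lm.chroms:
        rows = lm.bin_rows[c]
        pos = lm.pos_cM[c]
        last = -np.inf
        for r, p in zip(rows, pos):
            if p - last >= spacing_cM or last == -np.inf:
                keep.append(r)
                last = p
    return np.asarray(keep, dtype=int)


def _residualize(M: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Residuals of ``cols`` (n x k) against the design ``M`` (n x p)."""
    beta, *_ = np.linalg.lstsq(M, cols, rcond=None)
    return cols - M @ beta


def select_cofactors(
    y: np.ndarray,
    C: np.ndarray,
    max_cofactors: int = 5,
    p_enter: float = 0.05,
    p_remove: float = 0.05,
) -> list[int]:
    """Forward-backward stepwise selection of background bins.

    ``C`` is (n_lines, n_candidates).  Forward steps add the candidate with
    the smallest partial-F p-value below ``p_enter`` (ties broken toward
    the lower column index); backward steps drop selected columns whose
    p-value rises above ``p_remove``.  Deterministic given the input.
    Collinear candidates (zero residual variance) are never added.
    """
    from scipy import stats

    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("at least 10 informative lines required")
    selected: list[int] = []
    seen: set[tuple[int, ...]] = set()
    while True:
        state = tuple(sorted(selected))
        if state in seen:  # add/drop oscillation guard
            break
        seen.add(state)
        M = np.column_stack([np.ones(n)] + [C[:, j] for j in selected])
        p_model = M.shape[1]
        ry = _residualize(M, y[:, None])[:, 0]
        dof = n - p_model - 1
        if dof < 1:
            break
        changed = False
        if len(selected) < max_cofactors:
            rest = [j for j in range(C.shape[1]) if j not in selected]
            if rest:
                RC = _residualize(M, C[:, rest])
                ssc = np.einsum("ij,ij->j", RC, RC)
                ssy = float(ry @ ry)
                with np.errstate(invalid="ignore", divide="ignore"):
                    rho2 = np.where(
                        (ssc > 1e-10 * n) & (ssy > 0),
                        (RC.T @ ry) ** 2 / np.maximum(ssc * ssy, 1e-300),
                        0.0,
                    )
                rho2 = np.clip(rho2, 0.0, 1.0 - 1e-12)
                fstat = rho2 * dof / (1 - rho2)
                pvals = stats.f.sf(fstat, 1, dof)
                best = int(np.argmin(pvals))
                if pvals[best] < p_enter:
                    selected.append(rest[best])
                    changed = True
        # backward elimination on the refitted model
        if selected:
            M = np.column_stack([np.ones(n)] + [C[:, j] for j in selected])
            dof = n - M.shape[1]
            if dof >= 1:
                worst_p, worst_j = -1.0, None
                Q, R = np.linalg.qr(M)
                beta = np.linalg.solve(R, Q.T @ y)
                resid = y - M @ beta
                s2 = float(resid @ resid) / dof
                Rinv = np.linalg.inv(R)
                var_beta = s2 * np.sum(Rinv**2, axis=1)
                tstat2 = beta[1:] ** 2 / np.maximum(var_beta[1:], 1e-300)
                pv = stats.f.sf(tstat2, 1, dof)
                worst = int(np.argmax(pv))
                if pv[worst] > p_remove:
                    worst_p, worst_j = pv[worst], selected[worst]
                if worst_j is not None:
                    selected.remove(worst_j)
                    changed = True
        if not changed or len(selected) >= max_cofactors:
            break
    return selected


def cim_scan(
    y: np.ndarray,
    grid: ScanGrid,
    cofactor_scores: np.ndarray | None = None,
    cofactor_chrom: np.ndarray | None = None,
    cofactor_pos: np.ndarray | None = None,
    window: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """LOD curve and per-position additive-effect estimates.

    At each pseudo-position the trait is regressed on x-hat plus the
    cofactors, excluding cofactors within ``window / 2`` cM of the test
    position on the same chromosome.  ``window = inf`` with no cofactors
    reduces to simple interval mapping.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = 0 if cofactor_scores is None else cofactor_scores.shape[1]
    if k == 0:
        masks = np.zeros((1, grid.n_positions), dtype=bool)
        active_sets = [()]
        which = np.zeros(grid.n_positions, dtype=int)
    else:
        # excluded[c, t] — cofactor c masked at position t
        excl = np.zeros((k, grid.n_positions), dtype=bool)
        for c in range(k):
            same = grid.chrom_of == cofactor_chrom[c]
            excl[c] = same & (np.abs(grid.pos_cM - cofactor_pos[c]) < window / 2.0)
        keys = {}
        which = np.empty(grid.n_positions, dtype=int)
        for t in range(grid.n_positions):
            key = excl[:, t].tobytes()
            if key not in keys:
                keys[key] = len(keys)
            which[t] = keys[key]
        active_sets = [None] * len(keys)
        for key, gi in keys.items():
            mask = np.frombuffer(key, dtype=bool)
            active_sets[gi] = tuple(np.flatnonzero(~mask))
    lod = np.zeros(grid.n_positions)
    effect = np.zeros(grid.n_positions)
    for gi, active in enumerate(active_sets):
        cols = np.flatnonzero(which == gi)
        if len(cols) == 0:
            continue
        M = np.ones((n, 1)) if not active else np.column_stack(
            [np.ones(n), cofactor_scores[:, list(active)]]
        )
        if n <= M.shape[1] + 1:
            log.info("cim_scan: fewer lines than parameters; positions skipped")
            continue
        ry = _residualize(M, y[:, None])[:, 0]
        RX = _residualize(M, grid.X[:, cols])
        ssy = float(ry @ ry)
        ssx = np.einsum("ij,ij->j", RX, RX)
        sxy = RX.T @ ry
        with np.errstate(invalid="ignore", divide="ignore"):
            rho2 = np.where((ssx > 1e-12 * n) & (ssy > 0), sxy**2 / np.maximum(ssx * ssy, 1e-300), 0.0)
            eff = np.where(ssx > 1e-12 * n, sxy / np.maximum(ssx, 1e-300), 0.0)
        rho2 = np.clip(rho2, 0.0, 1.0 - 1e-15)
        lod[cols] = -(n / 2.0) * np.log10(1.0 - rho2)
        effect[cols] = eff
    return lod, effect


def permutation_threshold(
    y: np.ndarray,
    grid: ScanGrid,
    candidate_scores: np.ndarray,
    candidate_chrom: np.ndarray,
    candidate_pos: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    window: float = 10.0,
    reselect: bool = True,
    fixed_cofactors: list[int] | None = None,
    max_cofactors: int = 5,
    p_enter: float = 0.05,
    p_remove: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD threshold from trait permutations.

    The trait is permuted across lines ``n_perm`` times; cofactors are
    re-selected per permutation (conservative default) or held fixed; the
    threshold is the empirical (1 - alpha) quantile of the per-permutation
    maximum genome-wide LOD.  Returns ``(threshold, per-permutation maxima)``.
    """
    if n_perm < 20:
        raise ValueError("insufficient permutations (n_perm < 20)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        if reselect:
            cof = select_cofactors(yp, candidate_scores, max_cofactors, p_enter, p_remove)
        else:
            cof = fixed_cofactors or []
        lod, _ = cim_scan(
            yp,
            grid,
            candidate_scores[:, cof] if cof else None,
            candidate_chrom[cof] if cof else None,
            candidate_pos[cof] if cof else None,
            window,
        )
        maxima[b] = lod.max()
    return float(np.quantile(maxima, 1.0 - alpha, method="higher")), maxima


def _find_peaks(lod: np.ndarray, threshold: float, lod_drop: float) -> list[int]:
    """Indices of QTL peaks on one chromosome's LOD curve.

    Contiguous supra-threshold segments are split at valleys deeper than
    ``lod_drop`` below both adjacent peaks; plateau ties resolve to the
    lower position.
    """
    above = lod >= threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    segments = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    peaks: list[int] = []
    for seg in segments:
        # local maxima within the segment; a plateau is a peak at its first
        # index when strictly above both neighbouring values (segment edges
        # count as -inf, so a monotone run ending at an edge peaks there)
        cand = []
        i = seg[0]
        while i <= seg[-1]:
            j = i
            while j < seg[-1] and lod[j + 1] == lod[i]:
                j += 1
            left = lod[i - 1] if i > seg[0] else -np.inf
            right = lod[j + 1] if j < seg[-1] else -np.inf
            if lod[i] > left and lod[i] > right:
                cand.append(i)
            i = j + 1
        if not cand:
            cand = [int(seg[np.argmax(lod[seg])])]
        # merge peaks not separated by a sufficient dip
        cand = sorted(set(int(v) for v in cand))
        merged = True
        while merged and len(cand) > 1:
            merged = False
            for a, b in zip(cand[:-1], cand[1:]):
                valley = lod[a : b + 1].min()
                if valley > min(lod[a], lod[b]) - lod_drop:
                    drop = b if lod[b] < lod[a] or (lod[b] == lod[a]) else a
                    cand.remove(drop)
                    merged = True
                    break
        peaks.extend(cand)
    return sorted(peaks)


def summarize_qtl(
    lod: np.ndarray,
    effect: np.ndarray,
    grid: ScanGrid,
    threshold: float,
    n_lines: int,
    trait: str = "T",
    year: int | None = None,
    lod_drop: float = 1.5,
) -> pd.DataFrame:
    """QTL records from a LOD curve: peak, 1.5-LOD support interval,
    additive effect and PVE.  Named ``<trait><chrom>-<ordinal>`` with
    ordinals by position within a chromosome."""
    records = []
    for ci, chrom in enumerate(grid.chroms):
        cols = grid.chrom_positions(ci)
        clod = lod[cols]
        peaks = _find_peaks(clod, threshold, lod_drop)
        for ordinal, pk in enumerate(peaks, start=1):
            peak_lod = clod[pk]
            lo = pk
            while lo > 0 and clod[lo - 1] >= peak_lod - lod_drop:
                lo -= 1
            hi = pk
            while hi < len(clod) - 1 and clod[hi + 1] >= peak_lod - lod_drop:
                hi += 1
            pve = 1.0 - 10.0 ** (-2.0 * peak_lod / n_lines)
            records.append(
                {
                    "trait": trait,
                    "year": year,
                    "qtl": f"{trait}{chrom}-{ordinal}",
                    "chrom": chrom,
                    "lod": float(peak_lod),
                    "pos_cM": float(grid.pos_cM[cols[pk]]),
                    "ci_lo_cM": float(grid.pos_cM[cols[lo]]),
                    "ci_hi_cM": float(grid.pos_cM[cols[hi]]),
                    "additive_effect": float(effect[cols[pk]]),
                    "pve": float(pve),
                    "pve_r2": float(pve),  # identical in the regression formulation
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "trait", "year", "qtl", "chrom", "lod", "pos_cM",
            "ci_lo_cM", "ci_hi_cM", "additive_effect", "pve", "pve_r2",
        ],
    )


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------


@dataclass
class CIMScanModel:
    """Composite interval mapping model for one trait.

    Construct from a trait vector aligned to the bin-matrix lines, a scan
    grid and the bin matrix; ``fit()`` selects cofactors, scans the
    genome, computes the permutation threshold and returns a
    :class:`CIMScanResults`.
    """

    y: np.ndarray
    grid: ScanGrid
    bm: BinMatrix
    lm: LinkageMap
    trait: str = "trait"
    year: int | None = None
    window_cM: float = 10.0
    walk_step: float = 1.0
    max_cofactors: int = 5
    p_enter: float = 0.05
    p_remove: float = 0.05
    candidate_spacing_cM: float = 2.0
    lod_drop: float = 1.5
    _cand: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_trait_table(
        cls,
        tt: pd.DataFrame,
        trait: str,
        year: int,
        lm: LinkageMap,
        bm: BinMatrix,
        grid: ScanGrid | None = None,
        **kwargs,
    ) -> "CIMScanModel":
        """Build from the long trait table, aggregating replicates to line
        means and aligning lines to the bin matrix."""
        from .traits import line_year_means

        wide = line_year_means(tt)
        sub = wide.xs(year, level="year")[trait]
        missing = [s for s in bm.samples if s not in sub.index]
        if missing:
            raise ValueError(f"trait table lacks lines {missing[:5]}...")
        y = sub.loc[bm.samples].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("missing trait values; impute or drop lines first")
        if grid is None:
            grid = build_scan_grid(lm, bm, kwargs.get("walk_step", 1.0))
        return cls(y=y, grid=grid, bm=bm, lm=lm, trait=trait, year=year, **kwargs)

    def _candidates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        rows = candidate_bins(self.lm, self.candidate_spacing_cM)
        scores = bin_scores(self.bm)[:, rows]
        chrom_index = {c: i for i, c in enumerate(self.lm.chroms)}
        pos = np.empty(len(rows))
        chrom = np.empty(len(rows), dtype=int)
        lookup = {}
        for c in self.lm.chroms:
            for r, p in zip(self.lm.bin_rows[c], self.lm.pos_cM[c]):
                lookup[r] = (chrom_index[c], p)
        for i, r in enumerate(rows):
            chrom[i], pos[i] = lookup[r]
        return rows, scores, chrom, pos

    def fit(
        self,
        n_perm: int = 1000,
        alpha: float = 0.05,
        seed: int | np.random.Generator | None = None,
        threshold: float | None = None,
    ) -> "CIMScanResults":
        """Cofactor selection, genome scan and permutation threshold.

        ``threshold`` overrides the permutation threshold (n_perm then
        ignored), e.g. for re-using a threshold across traits.
        """
        rows, scores, cchrom, cpos = self._candidates()
        cof = select_cofactors(
            self.y, scores, self.max_cofactors, self.p_enter, self.p_remove
        )
        lod, effect = cim_scan(
            self.y,
            self.grid,
            scores[:, cof] if cof else None,
            cchrom[cof] if cof else None,
            cpos[cof] if cof else None,
            self.window_cM,
        )
        maxima = None
        if threshold is None:
            threshold, maxima = permutation_threshold(
                self.y,
                self.grid,
                scores,
                cchrom,
                cpos,
                n_perm=n_perm,
                alpha=alpha,
                seed=seed,
                window=self.window_cM,
                max_cofactors=self.max_cofactors,
                p_enter=self.p_enter,
                p_remove=self.p_remove,
            )
        return CIMScanResults(
            model=self,
            lod=lod,
            effects=effect,
            threshold=float(threshold),
            perm_maxima=maxima,
            cofactor_bins=[int(rows[j]) for j in cof],
            alpha=alpha,
        )


@dataclass
class CIMScanResults:
    """Fitted CIM scan: LOD profile, threshold and QTL records."""

    model: CIMScanModel
    lod: np.ndarray
    effects: np.ndarray
    threshold: float
    perm_maxima: np.ndarray | None
    cofactor_bins: list[int]
    alpha: float

    def qtl_table(self) -> pd.DataFrame:
        return summarize_qtl(
            self.lod,
            self.effects,
            self.model.grid,
            self.threshold,
            n_lines=len(self.model.y),
            trait=self.model.trait,
            year=self.model.year,
            lod_drop=self.model.lod_drop,
        )

    def lod_frame(self) -> pd.DataFrame:
        g = self.model.grid
        return pd.DataFrame(
            {
                "chrom": [g.chroms[i] for i in g.chrom_of],
                "pos_cM": g.pos_cM,
                "lod": self.lod,
                "effect": self.effects,
            }
        )

    def summary(self) -> str:
        qt = self.qtl_table()
        lines = [
            f"Composite interval mapping: {self.model.trait}"
            + (f" (year {self.model.year})" if self.model.year else ""),
            f"  lines: {len(self.model.y)}   positions: {self.model.grid.n_positions}"
            f"   cofactors: {len(self.cofactor_bins)}",
            f"  genome-wide LOD threshold (alpha={self.alpha}): {self.threshold:.2f}",
            f"  QTLs detected: {len(qt)}",
        ]
        if len(qt):
            lines.append(
                qt[
                    ["qtl", "chrom", "lod", "pos_cM", "ci_lo_cM", "ci_hi_cM",
                     "additive_effect", "pve"]
                ].to_string(index=False, float_format=lambda v: f"{v:.2f}")
            )
        return "\n".join(lines)

    def plot_lod(self, ax=None):
        """LOD profile with the threshold line, one panel of concatenated
        chromosomes (matplotlib Axes returned)."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(10, 3))
        g = self.model.grid
        offset = 0.0
        for ci, c in enumerate(g.chroms):
            cols = g.chrom_positions(ci)
            ax.plot(g.pos_cM[cols] + offset, self.lod[cols], lw=1.0, label=str(c))
            offset += g.pos_cM[cols].max() + 5
        ax.axhline(self.threshold, color="red", ls="--", lw=0.8)
        ax.set_xlabel("map position (cM, chromosomes concatenated)")
        ax.set_ylabel("LOD")
        ax.set_title(self.model.trait)
        return ax
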