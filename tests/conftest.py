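"""Shared fixtures: a small simulated BIL population and its pipeline products."""

import numpy as np
import pytest

from bilqtl import (
    SimConfig,
    assemble_map,
    breed_bil,
    build_bins,
    call_tracks,
    filter_distortion,
    filter_snps,
    make_founders,
    observe_snp_calls,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_chromosomes=2,
        chrom_len_bp=10_000_000,
        chrom_len_cM=100.0,
        n_snps_per_chrom=2000,
        n_lines=60,
        n_bc2=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_population(small_cfg):
    founders = make_founders(small_cfg)
    truth = breed_bil(founders, small_cfg)
    raw = observe_snp_calls(truth, founders, small_cfg)
    return founders, truth, raw


@pytest.fixture(scope="session")
def small_panel(small_population, small_cfg):
    _, _, raw = small_population
    return filter_snps(raw, min_line_fraction=0.55)


@pytest.fixture(scope="session")
def small_bins(small_panel):
    tracks = call_tracks(small_panel)
    site_pos = {
        c: small_panel.sites["pos"].to_numpy()[small_panel.chrom_slice(c)]
        for c in small_panel.chroms
    }
    bm = filter_distortion(build_bins(tracks, site_pos))
    return tracks, bm


@pytest.fixture(scope="session")
def small_map(small_bins):
    _, bm = small_bins
    return assemble_map(bm)


def single_locus_oracle(n_backcross: int = 2, n_selfs: int = 6) -> np.ndarray:
    """Independent pedigree oracle: genotype distribution (AA, het, BB) by
    explicit transition matrices applied to the F1 state vector."""
    backcross = np.array(
        [
            [1.0, 0.5, 0.0],  # to AA
            [0.0, 0.5, 0.0],  # to het
            [0.0, 0.0, 0.0],  # BB x AA cannot stay BB: becomes het
        ]
    )
    # a BB plant backcrossed to AA gives het offspring
    backcross[1, 2] = 1.0
    selfing = np.array(
        [
            [1.0, 0.25, 0.0],
            [0.0, 0.50, 0.0],
            [0.0, 0.25, 1.0],
        ]
    )
    p = np.array([0.0, 1.0, 0.0])
    for _ in range(n_backcross):
        p = backcross @ p
    for _ in range(n_selfs):
        p = selfing @ p
    return p


def collapse_short_segments(runs, min_len):
    """Project a true genotype track to the stated resolution.

    Segments shorter than ``min_len`` (one bin-grid interval) cannot be
    represented by any method operating at that grid; they are merged into
    their neighbours (equal-genotype neighbours coalesce, opposite ones
    meet at the segment centre).  Returns the surviving breakpoints.
    """
    runs = [list(r) for r in runs]
    changed = True
    while changed and len(runs) > 1:
        changed = False
        order = sorted(range(len(runs)), key=lambda i: runs[i][1] - runs[i][0])
        i = order[0]
        s, e, g = runs[i]
        if e - s >= min_len:
            break
        if i == 0:
            runs[1][0] = s
            runs.pop(0)
        elif i == len(runs) - 1:
            runs[-2][1] = e
            runs.pop()
        else:
            left, right = runs[i - 1], runs[i + 1]
            if left[2] == right[2]:
                left[1] = right[1]
                runs.pop(i)
                runs.pop(i)
            else:
                mid = (s + e) / 2
                left[1] = mid
                right[0] = mid
                runs.pop(i)
        changed = True
        # merge equal adjacent runs
        j = 1
        while j < len(runs):
            if runs[j][2] == runs[j - 1][2]:
                runs[j - 1][1] = runs[j][1]
                runs.pop(j)
            else:
                j += 1
    return np.array([r[0] for r in runs[1:]])


def match_breakpoints(true_bp, got_bp, tol):
    """Greedy 1-1 matching; returns (n_true, n_matched, n_spurious)."""
    used = np.zeros(len(got_bp), bool)
    matched = 0
    for t in true_bp:
        if len(got_bp) == 0:
            continue
        cost = np.abs(got_bp - t) + used * 1e15
        j = int(np.argmin(cost))
        if not used[j] and abs(got_bp[j] - t) <= tol:
            used[j] = True
            matched += 1
    return len(true_bp), matched, int((~used).sum())


def breakpoint_recovery_errors(track_runs, got_bp, grid):
    """(n_resolvable, n_missed, n_spurious) for one line and chromosome.

    Spurious calls are judged against the raw truth (a recovered sub-grid
    segment is correct, not spurious); completeness is judged against the
    grid-collapsed truth (segments below one grid interval are not
    representable at bin resolution).
    """
    raw_bp = np.array([r[0] for r in track_runs[1:]])
    collapsed = collapse_short_segments(track_runs, grid)
    _, _, n_spurious = match_breakpoints(raw_bp, got_bp, grid)
    n_res, n_hit, _ = match_breakpoints(collapsed, got_bp, grid)
    return n_res, n_res - n_hit, n_spurious


def window_oracle(calls, window, majority=2.0 / 3.0, min_informative=10):
    """Exhaustive per-window recount, independent of the vectorised caller."""
    from bilqtl import codes

    n = len(calls)
    w = min(window, n)
    out = []
    for start in range(0, n - w + 1):
        chunk = calls[start : start + w]
        a = sum(1.0 for c in chunk if c == codes.AA) + 0.5 * sum(
            1 for c in chunk if c == codes.HET
        )
        b = sum(1.0 for c in chunk if c == codes.BB) + 0.5 * sum(
            1 for c in chunk if c == codes.HET
        )
        inf = sum(1 for c in chunk if c != codes.MISSING)
        if inf < min_informative or a + b == 0:
            out.append(codes.MISSING)
        elif a / (a + b) > majority:
            out.append(codes.AA)
        elif b / (a + b) > majority:
            out.append(codes.BB)
        else:
            out.append(codes.HET)
    return np.array(out, dtype=np.int8)
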