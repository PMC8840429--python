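"""Forward simulation of a backcross inbred line (BIL) population.

The generator reproduces the breeding design the analysis assumes: a wild
donor (Ws) is crossed to a recurrent cultivar parent (Af); the F1 is
backcrossed to Af twice (80 BC1 plants of which 65 are kept, then 302 BC2
plants) and each BC2 plant is selfed for six generations by single-seed
descent, after which 110 lines are sampled.  Meiosis follows the Haldane
model: crossover counts are Poisson with mean equal to the map length in
Morgans and crossover positions are uniform in genetic distance (no
interference).  The recombination landscape is uniform by default, i.e. the
genetic coordinate of a site is ``chrom_len_cM * bp / chrom_len_bp``.

Sequencing is emulated with a read-sampling observation model: per site and
line the read depth is Poisson (≈1.8x for lines, ≈10x for parents), each
read draws an allele from the true genotype (fair coin for heterozygotes)
and is flipped with a per-read error probability; the genotype call is
homozygous when all reads agree, heterozygous when both alleles are seen
and missing at depth zero.

Phenotypes are additive: trait value = intercept + sum of planted QTL
effects (x = +1 for the Af homozygote, -1 for the Ws homozygote, 0 for a
heterozygote) + a year shift + Gaussian residual per replicate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import codes
from .panel import SNPCallMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "FounderGenome",
    "TrueGenotypeSet",
    "QTLEffect",
    "QTLSpec",
    "make_founders",
    "simulate_gamete",
    "breed_bil",
    "observe_snp_calls",
    "simulate_phenotypes",
    "expected_genotype_freqs",
    "genotype_score_variance",
    "additive_for_pve",
    "default_qtl_spec",
]

_BASES = np.array(list("ACGT"))


def _as_per_chrom(value, n: int, dtype=float) -> np.ndarray:
    arr = np.asarray(value, dtype=dtype)
    if arr.ndim == 0:
        arr = np.full(n, arr)
    if arr.shape != (n,):
        raise ValueError(f"expected scalar or length-{n} sequence, got shape {arr.shape}")
    return arr


@dataclass
class SimConfig:
    """Population-design and observation parameters.

    Defaults are the study conditions of the carrot BIL design: 9
    chromosomes, BC2S6 pedigree (80 BC1 / 65 kept / 302 BC2 / 6 selfing
    generations / 110 lines), ~1.8x line depth, ~10x parent depth.  The
    genome itself is a desk-scale stand-in: 150 cM and 2,000 SNP sites per
    chromosome on a 20 Mb physical axis.
    """

    n_chromosomes: int = 9
    chrom_len_bp: float | Sequence[float] = 20_000_000
    chrom_len_cM: float | Sequence[float] = 150.0
    n_snps_per_chrom: int = 2000
    n_bc1: int = 80
    n_bc1_kept: int = 65
    n_bc2: int = 302
    n_self_generations: int = 6
    n_lines: int = 110
    mean_line_depth: float = 1.8
    parent_depth: float = 10.0
    genotype_error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "n_bc1", "n_bc1_kept", "n_bc2", "n_lines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_snps_per_chrom < 0:
            raise ValueError("n_snps_per_chrom must be >= 0")
        if self.n_self_generations < 0:
            raise ValueError("n_self_generations must be >= 0")
        if self.mean_line_depth < 0 or self.parent_depth < 0:
            raise ValueError("depths must be >= 0")
        if not 0 <= self.genotype_error_rate < 0.5:
            raise ValueError("genotype_error_rate must be in [0, 0.5)")
        if self.n_bc1_kept > self.n_bc1:
            raise ValueError("n_bc1_kept cannot exceed n_bc1")
        if np.any(self.len_bp <= 0) or np.any(self.len_cM < 0):
            raise ValueError("chromosome lengths must be positive")

    @property
    def len_bp(self) -> np.ndarray:
        return _as_per_chrom(self.chrom_len_bp, self.n_chromosomes)

    @property
    def len_cM(self) -> np.ndarray:
        return _as_per_chrom(self.chrom_len_cM, self.n_chromosomes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_len_bp"] = self.len_bp.tolist()
        d["chrom_len_cM"] = self.len_cM.tolist()
        return d


@dataclass
class FounderGenome:
    """Parental haplotype carrier: SNP positions and the two parental alleles.

    ``snp_positions`` are 1-based bp coordinates, strictly increasing per
    chromosome; ``cM_positions`` follow the (default uniform) recombination
    landscape.  ``allele_A`` is the Af (recurrent-parent) base at each site
    and ``allele_B`` the Ws base; they differ at every site.
    """

    snp_positions: list[np.ndarray]
    cM_positions: list[np.ndarray]
    allele_A: list[np.ndarray]
    allele_B: list[np.ndarray]
    chrom_len_bp: np.ndarray
    chrom_len_cM: np.ndarray

    @property
    def n_chromosomes(self) -> int:
        return len(self.snp_positions)

    def sites_frame(self) -> pd.DataFrame:
        frames = []
        for c in range(self.n_chromosomes):
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c + 1,
                        "pos": self.snp_positions[c],
                        "ref": self.allele_A[c],
                        "alt": self.allele_B[c],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def make_founders(config: SimConfig, rng: np.random.Generator | None = None) -> FounderGenome:
    """Draw SNP sites uniformly without replacement along each chromosome."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pos_l, cm_l, a_l, b_l = [], [], [], []
    for c in range(config.n_chromosomes):
        L = int(config.len_bp[c])
        n = config.n_snps_per_chrom
        if n > L:
            raise ValueError("too many sites: n_snps_per_chrom exceeds chrom_len_bp")
        pos = np.sort(rng.choice(L, size=n, replace=False)) + 1  # 1-based
        cm = config.len_cM[c] * pos / config.len_bp[c]
        ia = rng.integers(0, 4, size=n)
        ib = (ia + rng.integers(1, 4, size=n)) % 4  # guaranteed different base
        pos_l.append(pos.astype(np.int64))
        cm_l.append(cm)
        a_l.append(_BASES[ia])
        b_l.append(_BASES[ib])
    return FounderGenome(pos_l, cm_l, a_l, b_l, config.len_bp.copy(), config.len_cM.copy())


# ---------------------------------------------------------------------------
# haplotypes and meiosis
#
# A haplotype is (bounds, origins): origins[i] (0 = A/Af, 1 = B/Ws) applies on
# the half-open bp interval [bounds[i], bounds[i+1]); bounds[0] = 0 and
# bounds[-1] = chromosome length.
# ---------------------------------------------------------------------------

Haplotype = tuple[np.ndarray, np.ndarray]


def _hap(origin: int, length: float) -> Haplotype:
    return np.array([0.0, float(length)]), np.array([origin], dtype=np.int8)


def _origin_at(hap: Haplotype, pos_bp: np.ndarray) -> np.ndarray:
    bounds, origins = hap
    idx = np.searchsorted(bounds, pos_bp, side="right") - 1
    return origins[np.clip(idx, 0, len(origins) - 1)]


def simulate_gamete(
    diplotype: tuple[Haplotype, Haplotype],
    chrom_len_cM: float,
    chrom_len_bp: float,
    rng: np.random.Generator,
) -> Haplotype:
    """One meiotic product under the Haldane (no-interference) model.

    Crossover count ~ Poisson(chrom_len_cM / 100); positions uniform in cM
    (hence, with the default uniform landscape, uniform in bp); the gamete
    alternates between the two homologs at crossovers, starting from a
    fair-coin choice.
    """
    k = rng.poisson(chrom_len_cM / 100.0) if chrom_len_cM > 0 else 0
    cur = int(rng.integers(2))
    h0, h1 = diplotype
    if k == 0:
        return (h0 if cur == 0 else h1)[0].copy(), (h0 if cur == 0 else h1)[1].copy()
    xs = np.sort(rng.uniform(0.0, chrom_len_cM, size=k)) * (chrom_len_bp / chrom_len_cM)
    homs = (h0, h1)
    cuts = np.concatenate([[0.0], xs, [float(chrom_len_bp)]])
    out_bounds = [0.0]
    out_orig: list[int] = []
    for seg in range(len(cuts) - 1):
        lo, hi = cuts[seg], cuts[seg + 1]
        if hi > lo:
            bounds, origins = homs[cur]
            i = np.searchsorted(bounds, lo, side="right") - 1
            j = np.searchsorted(bounds, hi, side="left")
            inner = bounds[i + 1 : j]
            for b, o in zip(np.concatenate([inner, [hi]]), origins[i:j]):
                if out_orig and out_orig[-1] == o:
                    out_bounds[-1] = b
                else:
                    out_bounds.append(b)
                    out_orig.append(int(o))
        cur ^= 1
    return np.asarray(out_bounds), np.asarray(out_orig, dtype=np.int8)


Plant = list  # list over chromosomes of (Haplotype, Haplotype)


def _make_gamete(plant: Plant, config: SimConfig, rng: np.random.Generator) -> list[Haplotype]:
    return [
        simulate_gamete(plant[c], config.len_cM[c], config.len_bp[c], rng)
        for c in range(config.n_chromosomes)
    ]


@dataclass
class TrueGenotypeSet:
    """Latent founder-origin diplotypes for every line.

    This is the truth the bin map estimates: per line and chromosome, the
    two homologs as founder-origin segment tracks.
    """

    diplotypes: list[Plant]
    chrom_len_bp: np.ndarray
    chrom_len_cM: np.ndarray
    line_names: list[str]

    @property
    def n_lines(self) -> int:
        return len(self.diplotypes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_len_bp)

    def genotype_codes(self, founders: FounderGenome) -> np.ndarray:
        """True genotype code per line x site (sites concatenated over chroms)."""
        out = np.empty((self.n_lines, sum(len(p) for p in founders.snp_positions)), dtype=np.int8)
        for i, plant in enumerate(self.diplotypes):
            cols = []
            for c in range(self.n_chromosomes):
                pos = founders.snp_positions[c].astype(float)
                o0 = _origin_at(plant[c][0], pos)
                o1 = _origin_at(plant[c][1], pos)
                g = (o0 + o1).astype(np.int8)  # 0=AA, 1=het, 2=BB
                cols.append(np.where(g == 1, codes.HET, np.where(g == 0, codes.AA, codes.BB)))
            out[i] = np.concatenate(cols)
        return out

    def genotype_track(self, line: int, chrom: int) -> list[tuple[float, float, int]]:
        """Collapse the diplotype of one chromosome to (start, end, code) runs."""
        h0, h1 = self.diplotypes[line][chrom]
        bounds = np.unique(np.concatenate([h0[0], h1[0]]))
        mid = (bounds[:-1] + bounds[1:]) / 2
        g = _origin_at(h0, mid).astype(int) + _origin_at(h1, mid).astype(int)
        code = np.where(g == 1, codes.HET, np.where(g == 0, codes.AA, codes.BB))
        runs: list[tuple[float, float, int]] = []
        for s, e, c in zip(bounds[:-1], bounds[1:], code):
            if runs and runs[-1][2] == c:
                runs[-1] = (runs[-1][0], e, c)
            else:
                runs.append((s, e, int(c)))
        return runs

    def true_breakpoints(self, line: int, chrom: int) -> np.ndarray:
        """Genotype-track switch positions (bp) for one line and chromosome."""
        runs = self.genotype_track(line, chrom)
        return np.array([r[0] for r in runs[1:]])

    def heterozygosity(self, founders: FounderGenome) -> float:
        g = self.genotype_codes(founders)
        return float(np.mean(g == codes.HET))

    def to_json(self, path) -> None:
        payload = {
            "chrom_len_bp": self.chrom_len_bp.tolist(),
            "chrom_len_cM": self.chrom_len_cM.tolist(),
            "line_names": self.line_names,
            "diplotypes": [
                [
                    [[h[0].tolist(), h[1].tolist()] for h in pair]
                    for pair in plant
                ]
                for plant in self.diplotypes
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrueGenotypeSet":
        with open(path) as fh:
            payload = json.load(fh)
        dips = [
            [
                tuple(
                    (np.asarray(b), np.asarray(o, dtype=np.int8)) for b, o in pair
                )
                for pair in plant
            ]
            for plant in payload["diplotypes"]
        ]
        return cls(
            dips,
            np.asarray(payload["chrom_len_bp"]),
            np.asarray(payload["chrom_len_cM"]),
            payload["line_names"],
        )


def breed_bil(
    founders: FounderGenome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    selection: Callable[[Plant], float] | None = None,
) -> TrueGenotypeSet:
    """Execute the BC2S6 pedigree exactly.

    F1 = Ws x Af; BC1 = F1 x Af (``n_bc1`` plants, a random ``n_bc1_kept``
    retained); BC2 = BC1 x Af (``n_bc2`` plants, dams drawn uniformly from
    the kept BC1s); each BC2 plant is selfed ``n_self_generations`` times by
    single-seed descent; ``n_lines`` lines are sampled without replacement.

    ``selection`` is an optional viability hook: a function mapping a plant
    to a fitness in (0, 1]; offspring are accepted by rejection sampling at
    every generation (used to induce segregation distortion for testing).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.n_lines > config.n_bc2:
        raise ValueError("n_lines cannot exceed n_bc2")
    nchrom = config.n_chromosomes

    def af_plant() -> Plant:
        return [(_hap(0, config.len_bp[c]), _hap(0, config.len_bp[c])) for c in range(nchrom)]

    f1: Plant = [(_hap(1, config.len_bp[c]), _hap(0, config.len_bp[c])) for c in range(nchrom)]
    af = af_plant()

    def offspring(mother: Plant, father: Plant) -> Plant:
        while True:
            child = [
                (ga, gb)
                for ga, gb in zip(
                    _make_gamete(mother, config, rng), _make_gamete(father, config, rng)
                )
            ]
            if selection is None or rng.uniform() < selection(child):
                return child

    bc1 = [offspring(f1, af) for _ in range(config.n_bc1)]
    kept_idx = rng.choice(config.n_bc1, size=config.n_bc1_kept, replace=False)
    kept = [bc1[i] for i in kept_idx]
    dams = rng.integers(0, config.n_bc1_kept, size=config.n_bc2)
    plants = [offspring(kept[d], af) for d in dams]
    for _ in range(config.n_self_generations):
        plants = [offspring(p, p) for p in plants]
    chosen = np.sort(rng.choice(config.n_bc2, size=config.n_lines, replace=False))
    names = [f"L{i + 1:03d}" for i in range(config.n_lines)]
    return TrueGenotypeSet(
        [plants[i] for i in chosen], config.len_bp.copy(), config.len_cM.copy(), names
    )


def expected_genotype_freqs(n_backcross: int = 2, n_selfs: int = 6) -> np.ndarray:
    """Exact single-locus genotype distribution (AA, het, BB) of the pedigree.

    Closed form from the Mendelian transition rules: each backcross to the
    AA parent halves heterozygosity without creating BB; each selfing
    generation halves heterozygosity, splitting the loss evenly between the
    homozygotes.  For BC2S6 this gives P(BB) = (1/8)(1 - 2^-6) = 63/512.
    """
    p = np.array([0.0, 1.0, 0.0])  # F1: (AA, het, BB)
    for _ in range(n_backcross):
        p = np.array([p[0] + p[1] / 2, p[1] / 2, p[2]])
    for _ in range(n_selfs):
        p = np.array([p[0] + p[1] / 4, p[1] / 2, p[2] + p[1] / 4])
    return p


def genotype_score_variance(n_backcross: int = 2, n_selfs: int = 6) -> float:
    """Variance of the additive score x (+1 AA, 0 het, -1 BB) at a neutral locus."""
    p = expected_genotype_freqs(n_backcross, n_selfs)
    ex = p[0] - p[2]
    return float(p[0] + p[2] - ex**2)


def observe_snp_calls(
    truth: TrueGenotypeSet,
    founders: FounderGenome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SNPCallMatrix:
    """Low-coverage sequencing observation of the true genotypes.

    Depth ~ Poisson(mean_line_depth) per line x site (parents at
    ``parent_depth``); each read is drawn from the true genotype's alleles
    and flipped with ``genotype_error_rate``; a call is homozygous when all
    reads carry one allele, heterozygous when both are seen, missing at
    depth zero.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    sites = founders.sites_frame()
    g_true = truth.genotype_codes(founders)
    e = config.genotype_error_rate

    def observe(g: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
        depth = rng.poisson(lam, size=g.shape)
        p_a = np.where(g == codes.AA, 1 - e, np.where(g == codes.BB, e, 0.5))
        a_reads = rng.binomial(depth, p_a)
        calls = np.full(g.shape, codes.HET, dtype=np.int8)
        calls[a_reads == depth] = codes.AA
        calls[a_reads == 0] = codes.BB
        calls[depth == 0] = codes.MISSING
        return calls, depth.astype(np.int32)

    calls, depth = observe(g_true, config.mean_line_depth)
    n_sites = g_true.shape[1]
    g_parents = np.vstack(
        [np.full(n_sites, codes.AA, np.int8), np.full(n_sites, codes.BB, np.int8)]
    )
    p_calls, p_depth = observe(g_parents, config.parent_depth)
    sites["allele_a"] = sites["ref"]
    sites["allele_b"] = sites["alt"]
    return SNPCallMatrix(
        sites=sites,
        calls=calls,
        depth=depth,
        samples=list(truth.line_names),
        parent_calls=p_calls,
        parent_depth=p_depth,
        parent_names=("Af", "Ws"),
        oriented=True,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass
class QTLEffect:
    chrom: int  # 1-based
    pos_cM: float
    trait: str
    additive: float
    dominance: float = 0.0


@dataclass
class QTLSpec:
    """Planted QTLs plus the per-trait phenotype model."""

    qtls: list[QTLEffect]
    trait_means: dict[str, float]
    residual_sd: dict[str, float]
    year_shift: dict[str, float] = field(default_factory=dict)
    n_years: int = 2
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for t, sd in self.residual_sd.items():
            if sd <= 0:
                raise ValueError(f"residual SD for {t} must be > 0")


def additive_for_pve(
    pve: float, residual_sd: float, var_x: float | None = None
) -> float:
    """Additive effect giving a target PVE among line means.

    PVE = a^2 Var(x) / (a^2 Var(x) + sd^2) solved for a, with Var(x) from
    the exact BC2S6 pedigree distribution unless supplied.  ``residual_sd``
    is the residual standard deviation of the aggregated (line-mean) value.
    """
    if not 0 < pve < 1:
        raise ValueError("pve must be in (0, 1)")
    v = genotype_score_variance() if var_x is None else var_x
    return float(residual_sd * np.sqrt(pve / ((1 - pve) * v)))


#: measured traits with desk-scale intercepts, 2014->2015 shifts and replicate SDs
DEFAULT_TRAIT_MODEL: dict[str, tuple[float, float, float]] = {
    # trait: (mean, year shift, residual SD per replicate)
    "MLL": (54.3, 0.4, 8.0),
    "LW": (30.0, 8.0, 9.0),
    "RL": (17.2, 0.2, 3.2),
    "RSD": (3.3, 0.4, 0.6),
    "RMD": (2.6, 0.35, 0.5),
    "RTD": (1.2, 0.25, 0.3),
    "RW": (90.0, 25.0, 35.0),
    "PW": (120.0, 33.0, 42.0),
    "DMC": (12.4, -0.9, 2.2),
}


def default_qtl_spec(config: SimConfig | None = None, n_replicates: int = 3) -> QTLSpec:
    """Five planted QTLs echoing the magnitude of the stable chromosome-2 loci.

    Effects are sized from target PVEs (0.16-0.32) through
    :func:`additive_for_pve` on the line-mean residual SD.  Positions are
    defined on the default 9 x 150 cM genome; for a smaller simulated
    genome (``config`` given), loci on absent chromosomes are dropped and
    positions rescale proportionally to the chromosome length.
    """
    means = {t: v[0] for t, v in DEFAULT_TRAIT_MODEL.items()}
    shifts = {t: v[1] for t, v in DEFAULT_TRAIT_MODEL.items()}
    sds = {t: v[2] for t, v in DEFAULT_TRAIT_MODEL.items()}
    targets = [
        ("RL", 2, 44.9, 0.32),
        ("RSD", 2, 44.9, 0.30),
        ("DMC", 2, 44.9, 0.30),
        ("MLL", 2, 44.9, 0.26),
        ("RW", 8, 140.0, 0.16),
    ]
    qtls = []
    for t, c, pos, pve in targets:
        if config is not None:
            if c > config.n_chromosomes:
                continue
            pos = pos / 150.0 * config.len_cM[c - 1]
        qtls.append(
            QTLEffect(c, pos, t, additive_for_pve(pve, sds[t] / np.sqrt(n_replicates)))
        )
    return QTLSpec(qtls, means, sds, shifts, n_years=2, n_replicates=n_replicates)


def simulate_phenotypes(
    truth: TrueGenotypeSet,
    qtl: QTLSpec,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format trait table: (line, year, replicate, trait, value)."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    for q in qtl.qtls:
        if q.trait not in qtl.trait_means:
            raise ValueError(f"QTL references unknown trait {q.trait!r}")
        if not (1 <= q.chrom <= config.n_chromosomes):
            raise ValueError(f"QTL chromosome {q.chrom} outside the genome")
        if not (0 <= q.pos_cM <= config.len_cM[q.chrom - 1]):
            raise ValueError(f"QTL position {q.pos_cM} cM outside chromosome {q.chrom}")

    n = truth.n_lines
    genetic = {t: np.zeros(n) for t in qtl.trait_means}
    for q in qtl.qtls:
        c = q.chrom - 1
        bp = q.pos_cM / config.len_cM[c] * config.len_bp[c]
        x = np.empty(n)
        het = np.empty(n, dtype=bool)
        for i in range(n):
            h0, h1 = truth.diplotypes[i][c]
            o = int(_origin_at(h0, np.array([bp]))[0]) + int(_origin_at(h1, np.array([bp]))[0])
            x[i] = 1.0 if o == 0 else (-1.0 if o == 2 else 0.0)
            het[i] = o == 1
        genetic[q.trait] += q.additive * x + q.dominance * het

    records = []
    for trait, mu in qtl.trait_means.items():
        sd = qtl.residual_sd[trait]
        shift = qtl.year_shift.get(trait, 0.0)
        for year in range(1, qtl.n_years + 1):
            base = mu + genetic[trait] + (shift if year > 1 else 0.0)
            for rep in range(1, qtl.n_replicates + 1):
                vals = base + rng.normal(0.0, sd, size=n)
                records.append(
                    pd.DataFrame(
                        {
                            "line": truth.line_names,
                            "year": year,
                            "replicate": rep,
                            "trait": trait,
                            "value": vals,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)
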