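"""SNP call matrix container, I/O and the SNP retention filter.

A site is retained when (1) both parents are called homozygous for
different alleles and at least ``min_lines`` lines carry a call at the
site, and (2) the read depth of both parents exceeds fourfold (strictly,
i.e. depth >= 5).  After filtering, calls are oriented so that code A is
the recurrent-parent (Af) allele and code B the wild donor (Ws) allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import codes

log = logging.getLogger(__name__)

__all__ = ["SNPCallMatrix", "read_genotypes", "filter_snps", "write_vcf", "write_tsv"]


@dataclass
class SNPCallMatrix:
    """Per-site, per-individual biallelic genotype calls with read depth.

    ``calls`` is an int8 array of shape (n_lines, n_sites) using the codes
    in :mod:`bilqtl.codes`; ``parent_calls`` has two rows, the recurrent
    parent first.  ``oriented`` records whether code A means the
    recurrent-parent allele (True) or the VCF reference allele (False).
    ``depth`` may be None for dialects that do not carry depths (TSV).
    """

    sites: pd.DataFrame  # columns: chrom, pos (1-based), ref, alt
    calls: np.ndarray
    samples: list[str]
    parent_calls: np.ndarray
    parent_names: tuple[str, str]
    depth: np.ndarray | None = None
    parent_depth: np.ndarray | None = None
    oriented: bool = False
    n_dropped_multiallelic: int = 0

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls shape does not match samples x sites")
        if self.depth is not None and np.any((self.depth == 0) != (self.calls == codes.MISSING)):
            raise ValueError("depth 0 must coincide with missing calls")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_lines(self) -> int:
        return len(self.samples)

    @property
    def chroms(self) -> list:
        return list(pd.unique(self.sites["chrom"]))

    def chrom_slice(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())

    def take_sites(self, idx: np.ndarray) -> "SNPCallMatrix":
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            parent_calls=self.parent_calls[:, idx],
            parent_depth=None if self.parent_depth is None else self.parent_depth[:, idx],
        )


def read_genotypes(path, dialect: str | None = None, parents=("Af", "Ws")) -> SNPCallMatrix:
    """Read a genotype matrix from VCF (GT/DP) or the TSV matrix dialect.

    ``parents`` names the (recurrent, donor) parent columns.  Sites with
    more than two observed alleles are dropped with a logged count.  VCF
    coordinates are kept 1-based.
    """
    path = str(path)
    if dialect is None:
        dialect = "tsv" if path.endswith((".tsv", ".txt")) else "vcf"
    if dialect == "vcf":
        return _read_vcf(path, parents)
    if dialect == "tsv":
        return _read_tsv(path, parents)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: str, parents) -> SNPCallMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    for p in parents:
        if p not in samples:
            raise ValueError(f"unknown parent name {p!r}; VCF samples: {samples}")
    line_names = [s for s in samples if s not in parents]
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([codes.AA, codes.HET, codes.MISSING, codes.BB], dtype=np.int8)
    rows_chrom, rows_pos, rows_ref, rows_alt = [], [], [], []
    call_cols, depth_cols = [], []
    dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped += 1
            continue
        g = remap[np.asarray(v.gt_types)]
        dp = v.format("DP")
        d = np.asarray(v.gt_depths) if dp is None else np.asarray(dp)[:, 0]
        d = np.where(d < 0, 0, d)
        g = np.where(d == 0, codes.MISSING, g)
        d = np.where(g == codes.MISSING, 0, d)
        rows_chrom.append(v.CHROM)
        rows_pos.append(v.POS)
        rows_ref.append(v.REF)
        rows_alt.append(v.ALT[0])
        call_cols.append(g.astype(np.int8))
        depth_cols.append(d.astype(np.int32))
    if dropped:
        log.info("dropped %d multi-allelic/non-SNP sites", dropped)
    calls = np.array(call_cols).T if call_cols else np.empty((len(samples), 0), np.int8)
    depth = np.array(depth_cols).T if depth_cols else np.empty((len(samples), 0), np.int32)
    pidx = [samples.index(p) for p in parents]
    lidx = [samples.index(s) for s in line_names]
    sites = pd.DataFrame({"chrom": rows_chrom, "pos": rows_pos, "ref": rows_ref, "alt": rows_alt})
    return SNPCallMatrix(
        sites=sites,
        calls=calls[lidx],
        samples=line_names,
        parent_calls=calls[pidx],
        parent_names=tuple(parents),
        depth=depth[lidx],
        parent_depth=depth[pidx],
        oriented=False,
        n_dropped_multiallelic=dropped,
    )


def _read_tsv(path: str, parents) -> SNPCallMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    required = ["CHROM", "POS", "REF", "ALT"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"TSV matrix missing required column {col}")
    individuals = [c for c in df.columns if c not in required]
    for p in parents:
        if p not in individuals:
            raise ValueError(f"unknown parent name {p!r}")
    line_names = [c for c in individuals if c not in parents]

    def decode(col: pd.Series) -> np.ndarray:
        out = col.map(codes.CODE)
        if out.isna().any():
            i = int(out.index[out.isna()][0])
            raise ValueError(
                f"malformed genotype {col.iloc[i]!r} at record {i + 1} of {path}"
            )
        return out.to_numpy(dtype=np.int8)

    calls = np.vstack([decode(df[s]) for s in line_names]) if line_names else np.empty((0, len(df)), np.int8)
    pcalls = np.vstack([decode(df[p]) for p in parents])
    sites = pd.DataFrame(
        {"chrom": df["CHROM"], "pos": df["POS"].astype(int), "ref": df["REF"], "alt": df["ALT"]}
    )
    return SNPCallMatrix(
        sites=sites,
        calls=calls,
        samples=line_names,
        parent_calls=pcalls,
        parent_names=tuple(parents),
        oriented=True,  # TSV codes are A/B by definition
    )


def filter_snps(
    m: SNPCallMatrix,
    min_lines: int = 60,
    min_parent_depth_exclusive: int = 4,
    min_line_fraction: float | None = None,
) -> SNPCallMatrix:
    """Apply the SNP retention criteria and orient codes to A = Af allele.

    ``min_line_fraction``, if given, overrides ``min_lines`` with
    ``ceil(fraction * n_lines)`` (for simulated populations of other
    sizes).  Site order is preserved; the output may be empty.
    """
    if min_line_fraction is not None:
        min_lines = math.ceil(min_line_fraction * m.n_lines)
    pa, pb = m.parent_calls
    hom = np.isin(pa, (codes.AA, codes.BB)) & np.isin(pb, (codes.AA, codes.BB))
    polymorphic = hom & (pa != pb)
    called = (m.calls != codes.MISSING).sum(axis=0)
    keep = polymorphic & (called >= min_lines)
    if m.parent_depth is not None:
        keep &= (m.parent_depth > min_parent_depth_exclusive).all(axis=0)
    elif min_parent_depth_exclusive > 0:
        log.warning("parent depths unavailable; depth criterion skipped")
    out = m.take_sites(np.flatnonzero(keep))
    log.info("filter_snps: %d of %d sites retained", out.n_sites, m.n_sites)
    if not m.oriented:
        flip = out.parent_calls[0] == codes.BB  # recurrent parent carries the alt allele
        def orient(arr: np.ndarray) -> np.ndarray:
            flipped = np.where(arr == codes.MISSING, arr, 2 - arr)
            return np.where(flip[None, :], flipped, arr).astype(np.int8)
        out = replace(out, calls=orient(out.calls), parent_calls=orient(out.parent_calls))
        sites = out.sites.copy()
        sites["allele_a"] = np.where(flip, sites["alt"], sites["ref"])
        sites["allele_b"] = np.where(flip, sites["ref"], sites["alt"])
        out = replace(out, sites=sites, oriented=True)
    return out


def write_vcf(m: SNPCallMatrix, path) -> None:
    """Minimal VCF 4.2 with GT and DP, parents first."""
    gt_map = {codes.AA: "0/0", codes.HET: "0/1", codes.BB: "1/1", codes.MISSING: "./."}
    names = list(m.parent_names) + list(m.samples)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bilqtl\n")
        for chrom in m.chroms:
            idx = m.chrom_slice(chrom)
            length = int(m.sites["pos"].iloc[idx].max()) if len(idx) else 0
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, names)) + "\n")
        all_calls = np.vstack([m.parent_calls, m.calls])
        if m.depth is not None and m.parent_depth is not None:
            all_depth = np.vstack([m.parent_depth, m.depth])
        else:
            all_depth = np.where(all_calls == codes.MISSING, 0, 1)
        for j in range(m.n_sites):
            row = m.sites.iloc[j]
            fields = [
                str(row["chrom"]), str(int(row["pos"])), ".", str(row["ref"]), str(row["alt"]),
                ".", "PASS", ".", "GT:DP",
            ]
            fields += [f"{gt_map[int(c)]}:{int(d)}" for c, d in zip(all_calls[:, j], all_depth[:, j])]
            fh.write("\t".join(fields) + "\n")


def write_tsv(m: SNPCallMatrix, path) -> None:
    """TSV matrix dialect: CHROM, POS, REF, ALT, then one A/B/H/. column each."""
    df = pd.DataFrame(
        {
            "CHROM": m.sites["chrom"],
            "POS": m.sites["pos"],
            "REF": m.sites["ref"],
            "ALT": m.sites["alt"],
        }
    )
    for i, p in enumerate(m.parent_names):
        df[p] = [codes.LETTER[int(c)] for c in m.parent_calls[i]]
    for i, s in enumerate(m.samples):
        df[s] = [codes.LETTER[int(c)] for c in m.calls[i]]
    df.to_csv(path, sep="\t", index=False)
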