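"""Readers and writers for the formats the tool exchanges with the
GWAS ecosystem: VCF and PLINK1 bed/bim/fam genotypes, .fam-style
pedigrees, sparse kinship (GRM) triplets, phenotype tables, and result
tables with provenance headers.

Genotypes are always surfaced as counts of the effect allele (the VCF
ALT allele, stored as allele 1 of the bim file), streamed in variant
blocks so a genome never has to fit in memory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from . import __version__ as _pkg_version
from .pedigree import KinshipModel, Member, Pedigree

logger = logging.getLogger("romgei")

__all__ = [
    "VariantBlock",
    "read_genotypes",
    "write_vcf",
    "write_plink",
    "read_plink_metadata",
    "write_fam",
    "read_pedigree",
    "write_grm",
    "read_relatedness",
    "write_phenotypes",
    "read_phenotypes",
    "write_results",
    "align_samples",
]


@dataclass
class VariantBlock:
    """One block of variants: metadata plus an N x b dosage matrix."""

    start: int
    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # 1-based, VCF convention
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray  # float, NaN = missing
    samples: list[str]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def missing_rate(self) -> np.ndarray:
        return np.mean(~np.isfinite(self.genotypes), axis=0)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _iter_vcf_blocks(path: str, block_size: int):
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    buf: list[tuple] = []
    start = 0

    def flush(start):
        ids = np.array([b[0] for b in buf])
        chrom = np.array([b[1] for b in buf])
        pos = np.array([b[2] for b in buf], dtype=np.int64)
        ref = np.array([b[3] for b in buf])
        alt = np.array([b[4] for b in buf])
        G = np.column_stack([b[5] for b in buf]).astype(float)
        return VariantBlock(start, ids, chrom, pos, ref, alt, G, samples)

    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            logger.warning("skipping non-biallelic record %s:%s", v.CHROM, v.POS)
            continue
        g = np.asarray(v.gt_types, dtype=float)  # 0/1/2 alt copies, 3 = missing
        g[g == 3] = np.nan
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        buf.append((vid, v.CHROM, v.POS, v.REF, v.ALT[0], g))
        if len(buf) == block_size:
            yield flush(start)
            start += block_size
            buf = []
    if buf:
        yield flush(start)
    if n_skipped:
        logger.warning("skipped %d malformed/non-biallelic records", n_skipped)


def write_vcf(path, genotypes: np.ndarray, samples, ids=None, chrom=None, pos=None,
              ref=None, alt=None) -> None:
    """Write bi-allelic GT-only VCF (uncompressed text).

    ``genotypes`` is N x V counts of the ALT allele; NaN becomes './.'.
    """
    G = np.asarray(genotypes)
    n, v = G.shape
    ids = ids if ids is not None else [f"v{j}" for j in range(v)]
    chrom = chrom if chrom is not None else ["1"] * v
    pos = pos if pos is not None else np.arange(1, v + 1)
    ref = ref if ref is not None else ["A"] * v
    alt = alt if alt is not None else ["C"] * v
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=romgei {_pkg_version}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in samples) + "\n")
        for j in range(v):
            col = G[:, j]
            gts = "\t".join(
                "./." if not np.isfinite(x) else gt_map[int(x)] for x in col
            )
            fh.write(
                f"{chrom[j]}\t{int(pos[j])}\t{ids[j]}\t{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PLINK1 bed/bim/fam (2-bit SNP-major codec)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, packed little-endian within each byte:
#   00 = two copies of allele 1, 10 = one copy, 11 = zero copies, 01 = missing
_CODE_FOR_COUNT = {2: 0b00, 1: 0b10, 0: 0b11}
_COUNT_FOR_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(prefix, genotypes: np.ndarray, sample_table: pd.DataFrame,
                variant_table: pd.DataFrame) -> None:
    """Write PLINK1 bed/bim/fam.  ``genotypes`` holds counts of allele 1
    (the effect allele); ``sample_table`` needs columns fid/iid (father,
    mother, sex, phenotype optional), ``variant_table`` columns
    id/chrom/pos/a1/a2."""
    prefix = str(prefix)
    G = np.asarray(genotypes)
    n, v = G.shape
    fam = pd.DataFrame(
        {
            "fid": sample_table["fid"],
            "iid": sample_table["iid"],
            "father": sample_table.get("father", pd.Series(["0"] * n)).fillna("0"),
            "mother": sample_table.get("mother", pd.Series(["0"] * n)).fillna("0"),
            "sex": sample_table.get("sex", pd.Series([0] * n)),
            "phenotype": sample_table.get("phenotype", pd.Series([-9] * n)),
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": variant_table["chrom"],
            "id": variant_table["id"],
            "cm": 0,
            "pos": variant_table["pos"],
            "a1": variant_table["a1"],
            "a2": variant_table["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.empty(n, dtype=np.uint8)
        for j in range(v):
            col = G[:, j]
            for count, code in _CODE_FOR_COUNT.items():
                codes[col == count] = code
            codes[~np.isfinite(col.astype(float))] = 0b01
            packed = np.zeros(n_bytes, dtype=np.uint8)
            for k in range(4):
                part = codes[k::4]
                packed[: len(part)] |= part << (2 * k)
            fh.write(packed.tobytes())


def read_plink_metadata(prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = str(prefix)
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str, "id": str},
    )
    return fam, bim


def _iter_plink_blocks(prefix: str, block_size: int):
    fam, bim = read_plink_metadata(prefix)
    n, v = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    samples = list(fam["iid"])
    with open(str(prefix) + ".bed", "rb") as fh:
        if fh.read(3) != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK1 bed file")
        for start in range(0, v, block_size):
            stop = min(start + block_size, v)
            raw = np.frombuffer(fh.read(n_bytes * (stop - start)), dtype=np.uint8)
            raw = raw.reshape(stop - start, n_bytes)
            codes = np.zeros((stop - start, n), dtype=np.uint8)
            for k in range(4):
                chunk = (raw >> (2 * k)) & 0b11
                cols = np.arange(k, n, 4)
                codes[:, cols] = chunk[:, : len(cols)]
            G = _COUNT_FOR_CODE[codes].T  # N x b
            sub = bim.iloc[start:stop]
            yield VariantBlock(
                start,
                sub["id"].to_numpy(),
                sub["chrom"].to_numpy(),
                sub["pos"].to_numpy(),
                sub["a2"].to_numpy(),
                sub["a1"].to_numpy(),
                G,
                samples,
            )


def read_genotypes(path, block_size: int = 4096):
    """Stream :class:`VariantBlock` objects from a VCF (.vcf/.vcf.gz) or a
    PLINK1 fileset (path to the .bed file or the bare prefix).

    Variant order follows the file; positions stay 1-based.
    """
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        yield from _iter_vcf_blocks(p, block_size)
        return
    prefix = p[:-4] if p.endswith(".bed") else p
    if not Path(prefix + ".bed").exists():
        raise FileNotFoundError(f"no VCF or PLINK fileset at {path}")
    yield from _iter_plink_blocks(prefix, block_size)


# ---------------------------------------------------------------------------
# pedigree / kinship / phenotypes
# ---------------------------------------------------------------------------


def write_fam(ped: Pedigree, path) -> None:
    """Write the pedigree as a PLINK .fam-compatible table."""
    rows = [
        (m.fid, m.iid, m.father or "0", m.mother or "0", 0, -9)
        for m in ped.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_pedigree(path) -> Pedigree:
    """Read a .fam-style pedigree; members are re-ordered parents-first
    and generation indices are recomputed as pedigree depth."""
    tab = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    raw = {
        r.iid: (r.fid, None if r.father in ("0", None) else r.father,
                None if r.mother in ("0", None) else r.mother)
        for r in tab.itertuples()
    }
    depth: dict[str, int] = {}

    def get_depth(iid, trail=()):
        if iid in depth:
            return depth[iid]
        if iid in trail:
            raise ValueError(f"cyclic parentage at {iid}")
        fid, fa, mo = raw[iid]
        d = 1 if fa is None else 1 + max(get_depth(fa, trail + (iid,)),
                                         get_depth(mo, trail + (iid,)))
        depth[iid] = d
        return d

    for iid in raw:
        get_depth(iid)
    order = sorted(raw, key=lambda i: (raw[i][0], depth[i]))
    members = [Member(i, raw[i][0], raw[i][1], raw[i][2], depth[i]) for i in order]
    return Pedigree(members)


def write_grm(km: KinshipModel, path, sample_ids) -> None:
    """Write kinship coefficients as sparse triplets id1, id2, value
    (lower triangle including the diagonal)."""
    sample_ids = np.asarray(sample_ids)
    with open(path, "w") as fh:
        fh.write("id1\tid2\tvalue\n")
        for blk, idx in zip(km.blocks, km.indices):
            for a in range(len(idx)):
                for b in range(a + 1):
                    val = blk[a, b]
                    if val != 0.0:
                        fh.write(
                            f"{sample_ids[idx[a]]}\t{sample_ids[idx[b]]}\t{val:.10g}\n"
                        )


def read_relatedness(path, sample_ids) -> KinshipModel:
    """Sparse GRM triplets -> block-diagonal KinshipModel.

    Families are recovered as connected components of the nonzero
    pattern.  Symmetric duplicate entries that disagree by more than
    1e-8 raise; ids absent from ``sample_ids`` raise.
    """
    sample_ids = list(map(str, sample_ids))
    pos = {s: i for i, s in enumerate(sample_ids)}
    tab = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    missing = set(tab["id1"]).union(tab["id2"]) - set(sample_ids)
    if missing:
        raise ValueError(f"GRM ids absent from the sample table: {sorted(missing)[:10]}")
    n = len(sample_ids)
    i = tab["id1"].map(pos).to_numpy()
    j = tab["id2"].map(pos).to_numpy()
    v = tab["value"].to_numpy(dtype=float)
    seen: dict[tuple[int, int], float] = {}
    for a, b, val in zip(i, j, v):
        key = (min(a, b), max(a, b))
        if key in seen and abs(seen[key] - val) > 1e-8:
            raise ValueError(
                f"conflicting GRM entries for pair {sample_ids[key[0]]},{sample_ids[key[1]]}"
            )
        seen[key] = val
    rows = np.array([k[0] for k in seen] + [k[1] for k in seen if k[0] != k[1]])
    cols = np.array([k[1] for k in seen] + [k[0] for k in seen if k[0] != k[1]])
    vals = np.array(
        list(seen.values()) + [val for k, val in seen.items() if k[0] != k[1]]
    )
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    pattern = mat.copy()
    pattern.setdiag(1.0)
    n_comp, labels = connected_components(pattern, directed=False)
    family_ids, blocks, indices = [], [], []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        family_ids.append(f"cluster{c}")
        blocks.append(mat[np.ix_(idx, idx)].toarray())
        indices.append(idx)
    return KinshipModel(family_ids, blocks, indices, n)


def write_phenotypes(path, ids, fids, y, x1=None, x2=None, **extra) -> None:
    cols = {"id": ids, "family": fids, "y": y}
    if x1 is not None:
        cols["x1"] = x1
    if x2 is not None:
        cols["x2"] = x2
    cols.update(extra)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "family": str})


def align_samples(pheno_ids, geno_ids) -> np.ndarray:
    """Indices into ``geno_ids`` putting genotypes in phenotype order.

    The phenotype table is the master ordering; genotype samples not in
    it are dropped with a warning, phenotype samples missing from the
    genotypes are a hard error.
    """
    pheno_ids = [str(s) for s in pheno_ids]
    geno_ids = [str(s) for s in geno_ids]
    pos = {s: i for i, s in enumerate(geno_ids)}
    missing = [s for s in pheno_ids if s not in pos]
    if missing:
        raise ValueError(f"samples missing from genotypes: {missing[:10]}")
    extra = set(geno_ids) - set(pheno_ids)
    if extra:
        logger.warning("dropping %d genotype samples absent from phenotypes", len(extra))
    return np.array([pos[s] for s in pheno_ids], dtype=np.int64)


# ---------------------------------------------------------------------------
# results with provenance
# ---------------------------------------------------------------------------


def write_results(df: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """Result TSV with a provenance header (version, seed, config hash)."""
    lines = [f"#romgei_version={_pkg_version}"]
    if seed is not None:
        lines.append(f"#seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"#config_sha256={digest}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
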