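"""In-memory genotype matrix and plain-text VCF round-trip.

The matrix holds samples x biallelic SNVs as alternate-allele dosages
(0/1/2, -1 for missing) plus the per-call PL/DP fields and per-site
annotations (QUAL, QD, FS, SOR) the QC stage filters on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class VCFParseError(ValueError):
    """Malformed VCF input; message carries the offending line number."""


@dataclass
class GenotypeMatrix:
    samples: list[str]
    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int, 1-based
    ref: np.ndarray  # (n_sites,) str
    alt: np.ndarray  # (n_sites,) str
    dosage: np.ndarray  # (n_sites, n_samples) int8, -1 = missing
    pl: Optional[np.ndarray] = None  # (n_sites, n_samples, 3) int32, -1 = absent
    dp: Optional[np.ndarray] = None  # (n_sites, n_samples) int32
    qual: Optional[np.ndarray] = None
    qd: Optional[np.ndarray] = None
    fs: Optional[np.ndarray] = None
    sor: Optional[np.ndarray] = None
    multiallelic: Optional[np.ndarray] = None  # (n_sites,) bool
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.multiallelic is None:
            self.multiallelic = np.zeros(len(self.pos), dtype=bool)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError("dosage shape does not match sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Site subset / reorder by integer index or boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        sub = lambda a: None if a is None else a[index]
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[index],
            pl=sub(self.pl),
            dp=sub(self.dp),
            qual=sub(self.qual),
            qd=sub(self.qd),
            fs=sub(self.fs),
            sor=sub(self.sor),
            multiallelic=sub(self.multiallelic),
            chrom_lengths=dict(self.chrom_lengths),
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        sub = lambda a: None if a is None else a[:, index]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[:, index],
            pl=None if self.pl is None else self.pl[:, index],
            dp=sub(self.dp),
            qual=self.qual,
            qd=self.qd,
            fs=self.fs,
            sor=self.sor,
            multiallelic=self.multiallelic,
            chrom_lengths=dict(self.chrom_lengths),
        )

    def sort_sites(self) -> "GenotypeMatrix":
        """Order sites by (chromosome appearance order, position)."""
        chrom_rank = {c: i for i, c in enumerate(sorted(set(self.chrom)))}
        key = np.array([chrom_rank[c] for c in self.chrom], dtype=np.int64)
        order = np.lexsort((self.pos, key))
        return self.take_sites(order)


_GT_CODE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
            "1/1": 2, "1|1": 2}
_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Emit a VCFv4.2 text file with GT:PL:DP and INFO QD/FS/SOR."""
    lines = ["##fileformat=VCFv4.2"]
    for c in matrix.chromosomes():
        length = matrix.chrom_lengths.get(c)
        if length:
            lines.append(f"##contig=<ID={c},length={length}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines += [
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">',
        '##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred genotype likelihoods">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    has_pl = matrix.pl is not None
    has_dp = matrix.dp is not None
    fmt = "GT" + (":PL" if has_pl else "") + (":DP" if has_dp else "")
    for i in range(matrix.n_sites):
        qual = "." if matrix.qual is None else f"{matrix.qual[i]:.2f}"
        info = []
        for tag, arr in (("QD", matrix.qd), ("FS", matrix.fs), ("SOR", matrix.sor)):
            if arr is not None:
                info.append(f"{tag}={arr[i]:.3f}")
        info_s = ";".join(info) if info else "."
        calls = []
        for j in range(matrix.n_samples):
            parts = [_GT_STR[int(matrix.dosage[i, j])]]
            if has_pl:
                pl = matrix.pl[i, j]
                parts.append("." if pl[0] < 0 else ",".join(str(int(x)) for x in pl))
            if has_dp:
                parts.append(str(int(matrix.dp[i, j])))
            calls.append(":".join(parts))
        lines.append(
            f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
            f"{matrix.alt[i]}\t{qual}\tPASS\t{info_s}\t{fmt}\t" + "\t".join(calls)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` via cyvcf2.

    Multiallelic sites are loaded with a flag set (their dosages are kept as
    missing); downstream QC removes them.  Missing calls are preserved as -1.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error surface
        raise VCFParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    chrom, pos, ref, alt = [], [], [], []
    dosage, pls, dps = [], [], []
    qual, qd, fs, sor = [], [], [], []
    multi = []
    chrom_lengths = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        chrom_lengths[name] = int(length)
    n_line = 0
    try:
        for v in vcf:
            n_line += 1
            is_multi = len(v.ALT) > 1
            multi.append(is_multi)
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(v.ALT[0] if v.ALT else ".")
            if is_multi:
                dosage.append(np.full(len(samples), -1, dtype=np.int8))
            else:
                gt = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
                gt[gt == 3] = -1
                dosage.append(gt)
            try:
                pl = v.format("PL")
            except KeyError:
                pl = None
            if pl is not None and pl.shape[1] >= 3:
                pl = pl[:, :3].astype(np.int32)
                pl[pl < 0] = -1
            else:
                pl = np.full((len(samples), 3), -1, dtype=np.int32)
            pls.append(pl)
            try:
                dp = v.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                dp = np.full(len(samples), -1, dtype=np.int32)
            else:
                dp = dp.reshape(-1).astype(np.int32)
            dps.append(dp)
            qual.append(v.QUAL if v.QUAL is not None else np.nan)
            qd.append(_info_float(v, "QD"))
            fs.append(_info_float(v, "FS"))
            sor.append(_info_float(v, "SOR"))
    except Exception as exc:
        raise VCFParseError(f"parse error near record {n_line + 1}: {exc}") from exc
    n = len(pos)
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=(np.stack(dosage) if n else np.zeros((0, len(samples)), np.int8)),
        pl=(np.stack(pls) if n else np.zeros((0, len(samples), 3), np.int32)),
        dp=(np.stack(dps) if n else np.zeros((0, len(samples)), np.int32)),
        qual=np.array(qual, dtype=float),
        qd=np.array(qd, dtype=float),
        fs=np.array(fs, dtype=float),
        sor=np.array(sor, dtype=float),
        multiallelic=np.array(multi, dtype=bool),
        chrom_lengths=chrom_lengths,
    )


def _info_float(variant, tag: str) -> float:
    val = variant.INFO.get(tag)
    return float(val) if val is not None else np.nan
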