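"""Reference genotype panel and genome block partition.

The panel is the LD reference: a diploid dosage matrix (individuals x SNPs,
values 0/1/2) with per-SNP metadata.  It is read from, and written to, plain
VCF with GT fields.  The block partition is an ordered list of non-overlapping
half-open intervals used to group SNPs into regions for colocalization; on
disk it is a 3-column BED file (0-based starts), converted on read to the
internal 1-based half-open convention that matches VCF positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenotypePanel:
    """Reference dosage matrix with SNP metadata.

    ``dosages`` has shape ``(n_individuals, n_snps)`` with values in {0, 1, 2}
    counting copies of ``a1``.  SNP metadata arrays are parallel to columns.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    dosages: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape[1] != len(self.snp_id):
            raise ValueError("dosage matrix columns must match SNP metadata length")
        if len(set(self.snp_id)) != len(self.snp_id):
            raise ValueError("duplicate SNP ids in panel")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not nondecreasing on chromosome {c}")
        self._index = {s: i for i, s in enumerate(self.snp_id)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def freq(self) -> np.ndarray:
        """Sample frequency of the a1 allele per SNP."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.freq
        return np.minimum(f, 1 - f)

    def indices_of(self, snp_ids) -> np.ndarray:
        """Column indices for the given ids; -1 where the panel lacks the SNP."""
        return np.array([self._index.get(s, -1) for s in snp_ids], dtype=np.int64)

    # --- VCF I/O -----------------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write the panel as an uncompressed VCF with unphased GT genotypes."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in dict.fromkeys(self.chrom):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(f"S{i:04d}" for i in range(self.n_individuals))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            gt_strings = np.array(["0/0", "0/1", "1/1"], dtype=object)
            for j in range(self.n_snps):
                # a1 (the dosage-counted allele) is written as ALT
                gts = gt_strings[self.dosages[:, j].astype(int)]
                fh.write(
                    f"{self.chrom[j]}\t{self.pos[j]}\t{self.snp_id[j]}\t"
                    f"{self.a2[j]}\t{self.a1[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypePanel":
        """Read a panel from VCF (phased or unphased GT); ALT is the counted allele."""
        from cyvcf2 import VCF

        ids, chroms, pos, a1, a2, rows = [], [], [], [], [], []
        vcf = VCF(str(path))
        for v in vcf:
            if len(v.ALT) != 1:
                logger.warning("skipping multi-allelic site %s", v.ID)
                continue
            ids.append(v.ID)
            chroms.append(v.CHROM)
            pos.append(v.POS)
            a1.append(v.ALT[0])
            a2.append(v.REF)
            # gt_types is unreliable across ploidy conventions; count ALT alleles
            g = np.array(v.genotypes, dtype=object)
            dos = np.array([int(a) + int(b) for a, b, *_ in g], dtype=float)
            rows.append(dos)
        vcf.close()
        return cls(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                   np.array(pos), np.array(a1, dtype=object), np.array(a2, dtype=object),
                   np.column_stack(rows) if rows else np.empty((0, 0)))


@dataclass
class BlockPartition:
    """Ordered, disjoint half-open genomic intervals [start, end), 1-based."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.end <= self.start):
            raise ValueError("block end must exceed start")
        for c in pd.unique(self.chrom):
            sel = self.chrom == c
            s, e = self.start[sel], self.end[sel]
            order = np.argsort(s, kind="stable")
            if np.any(e[order][:-1] > s[order][1:]):
                raise ValueError(f"overlapping blocks on chromosome {c}")

    def __len__(self) -> int:
        return len(self.start)

    @classmethod
    def from_bed(cls, path) -> "BlockPartition":
        """Read a 3-column BED; 0-based starts become 1-based half-open."""
        bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                          names=["chrom", "start", "end"], dtype={"chrom": str})
        logger.info("read %d blocks from %s (0-based BED starts shifted +1)", len(bed), path)
        return cls(bed["chrom"].to_numpy(), bed["start"].to_numpy() + 1,
                   bed["end"].to_numpy() + 1)

    def to_bed(self, path) -> None:
        pd.DataFrame({"chrom": self.chrom, "start": self.start - 1,
                      "end": self.end - 1}).to_csv(path, sep="\t", header=False, index=False)

    def assign(self, chrom, pos) -> np.ndarray:
        """Block index per SNP; -1 for positions outside every block.

        A SNP at position p belongs to the block with start <= p < end on its
        chromosome.
        """
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), -1, dtype=np.int64)
        for c in pd.unique(self.chrom):
            bsel = np.flatnonzero(self.chrom == c)
            order = np.argsort(self.start[bsel], kind="stable")
            bsel = bsel[order]
            starts, ends = self.start[bsel], self.end[bsel]
            ssel = np.flatnonzero(chrom == c)
            if len(ssel) == 0:
                continue
            k = np.searchsorted(starts, pos[ssel], side="right") - 1
            valid = (k >= 0) & (pos[ssel] < ends[np.clip(k, 0, None)])
            out[ssel[valid]] = bsel[k[valid]]
        return out


def assign_blocks(pair, blocks: BlockPartition) -> np.ndarray:
    """Per-SNP block index for a harmonized pair (-1 when unassigned)."""
    df = pair.df if hasattr(pair, "df") else pair
    idx = blocks.assign(df["chrom"].to_numpy(), df["pos"].to_numpy())
    n_out = int((idx < 0).sum())
    if n_out:
        logger.warning("%d SNPs fall outside the block partition", n_out)
    return idx
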