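"""GWAS summary-statistics tables: reading, validation, harmonization.

A summary-statistics table is a :class:`pandas.DataFrame` with the canonical
columns ``snp_id, chrom, pos, a1, a2, beta, se, pvalue, n, freq`` where ``a1``
is the effect allele, ``beta`` its per-allele effect estimate and ``freq`` its
allele frequency.  Two tables for different traits are merged on shared rsIDs
into a :class:`HarmonizedPair`, with trait-2 effects sign-flipped whenever its
alleles are recorded on the opposite orientation.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
SUMSTATS_COLUMNS = (
    "snp_id", "chrom", "pos", "a1", "a2", "beta", "se", "pvalue", "n", "freq",
)

_NUMERIC = ("pos", "beta", "se", "pvalue", "n", "freq")

#: smallest representable p-value; p == 0 rows are clamped here, not dropped,
#: so extreme GWAS hits survive the (0, 1] validity filter
MIN_PVALUE = sys.float_info.min

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: columns of a harmonized two-trait table
PAIR_COLUMNS = (
    "snp_id", "chrom", "pos", "a1", "a2",
    "beta1", "se1", "p1", "n1", "freq1",
    "beta2", "se2", "p2", "n2", "freq2",
    "flipped", "maf",
)


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce table invariants, dropping (and counting) offending rows.

    Rules: ``se > 0``; ``pvalue`` in (0, 1] with exact zeros clamped to the
    smallest positive float; finite ``beta``; ``a1 != a2``; unique ``snp_id``
    (first occurrence kept); ``freq`` strictly inside (0, 1).
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing mandatory columns: {missing}")
    df = df.loc[:, list(SUMSTATS_COLUMNS)].copy()
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)

    n_in = len(df)
    n_zero_p = int((df["pvalue"] == 0).sum())
    if n_zero_p:
        logger.warning("%d p-values of exactly 0 clamped to %.3e", n_zero_p, MIN_PVALUE)
        df.loc[df["pvalue"] == 0, "pvalue"] = MIN_PVALUE

    ok = (
        df[list(_NUMERIC)].notna().all(axis=1)
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & (df["freq"] > 0)
        & (df["freq"] < 1)
        & (df["a1"] != df["a2"])
    )
    df = df.loc[ok]
    df = df.drop_duplicates(subset="snp_id", keep="first")
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.warning("dropped %d of %d rows violating invariants", n_dropped, n_in)
    return df.reset_index(drop=True)


def read_sumstats(path, column_map: dict[str, str] | None = None, sep: str = "\t") -> pd.DataFrame:
    """Read a summary-statistics TSV and validate it.

    Parameters
    ----------
    path
        Tab-separated file with a header line.
    column_map
        Optional mapping from canonical name (e.g. ``"pvalue"``) to the name
        used in the file (e.g. ``"P"``).  Unmapped canonical names are taken
        verbatim.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        missing = [v for v in column_map.values() if v not in raw.columns]
        if missing:
            raise ValueError(f"mapped columns not in file: {missing}")
        raw = raw.rename(columns=rename)
    return validate_sumstats(raw)


def write_table(t: pd.DataFrame, path) -> None:
    """Write any tabular result as a TSV that round-trips through pandas."""
    if t is None or len(t) == 0:
        raise ValueError("refusing to write an empty table")
    t.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedPair:
    """Two traits' statistics joined on shared SNPs with alleles aligned.

    ``df`` carries one row per shared SNP (columns :data:`PAIR_COLUMNS`);
    ``audit`` records how the join treated each category of allele mismatch.
    """

    df: pd.DataFrame
    audit: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def trait(self, which: int) -> pd.DataFrame:
        """Recover a single trait's table in canonical sumstats layout."""
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2")
        k = str(which)
        out = self.df[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
        out["beta"] = self.df[f"beta{k}"].to_numpy()
        out["se"] = self.df[f"se{k}"].to_numpy()
        out["pvalue"] = self.df[f"p{k}"].to_numpy()
        out["n"] = self.df[f"n{k}"].to_numpy()
        out["freq"] = self.df[f"freq{k}"].to_numpy()
        return out

    def subset(self, mask) -> "HarmonizedPair":
        return HarmonizedPair(self.df.loc[mask].reset_index(drop=True), dict(self.audit))


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | (
        (a1 == "C") & (a2 == "G")) | ((a1 == "G") & (a2 == "C"))


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT).fillna(alleles)


def harmonize(s1: pd.DataFrame, s2: pd.DataFrame,
              drop_palindromic: bool = True) -> HarmonizedPair:
    """Join two validated tables on snp_id and align trait 2 to trait 1's alleles.

    Alignment cases per SNP (trait-1 alleles ``a1/a2``, trait-2 ``b1/b2``):

    * ``b1==a1, b2==a2`` — concordant, kept as-is;
    * ``b1==a2, b2==a1`` — swapped: ``beta2 := -beta2``, ``freq2 := 1-freq2``;
    * same two cases after complementing ``b1/b2`` (strand flip);
    * anything else is irreconcilable and dropped (counted).

    A/T and C/G palindromic SNPs are removed (strand orientation cannot be
    resolved from alleles alone).  Sign flips are recorded in the ``flipped``
    column; per-category counts land in ``audit``.
    """
    m = s1.merge(s2, on="snp_id", suffixes=("_1", "_2"), how="inner")
    audit = {"n_s1": len(s1), "n_s2": len(s2), "n_shared": len(m)}

    a1, a2 = m["a1_1"], m["a2_1"]
    b1, b2 = m["a1_2"], m["a2_2"]

    palin = _is_palindromic(a1, a2) | _is_palindromic(b1, b2)
    audit["n_palindromic_removed"] = int(palin.sum()) if drop_palindromic else 0
    if drop_palindromic:
        keep = ~palin
        m, a1, a2, b1, b2 = m[keep], a1[keep], a2[keep], b1[keep], b2[keep]

    b1c, b2c = _complement(b1), _complement(b2)
    same = (b1 == a1) & (b2 == a2)
    swapped = (b1 == a2) & (b2 == a1)
    same_c = (b1c == a1) & (b2c == a2) & ~same & ~swapped
    swapped_c = (b1c == a2) & (b2c == a1) & ~same & ~swapped
    flip = (swapped | swapped_c) & ~(same | same_c)
    ok = same | swapped | same_c | swapped_c
    audit["n_irreconcilable"] = int((~ok).sum())
    audit["n_flipped"] = int(flip[ok].sum())

    m = m[ok]
    flip = flip[ok].to_numpy()

    out = pd.DataFrame({
        "snp_id": m["snp_id"].to_numpy(),
        "chrom": m["chrom_1"].to_numpy(),
        "pos": m["pos_1"].to_numpy(),
        "a1": m["a1_1"].to_numpy(),
        "a2": m["a2_1"].to_numpy(),
        "beta1": m["beta_1"].to_numpy(),
        "se1": m["se_1"].to_numpy(),
        "p1": m["pvalue_1"].to_numpy(),
        "n1": m["n_1"].to_numpy(),
        "freq1": m["freq_1"].to_numpy(),
        "beta2": np.where(flip, -m["beta_2"].to_numpy(), m["beta_2"].to_numpy()),
        "se2": m["se_2"].to_numpy(),
        "p2": m["pvalue_2"].to_numpy(),
        "n2": m["n_2"].to_numpy(),
        "freq2": np.where(flip, 1 - m["freq_2"].to_numpy(), m["freq_2"].to_numpy()),
        "flipped": flip,
    })
    f = out["freq1"].to_numpy()
    out["maf"] = np.minimum(f, 1 - f)
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    audit["n_harmonized"] = len(out)
    logger.info("harmonize: %s", audit)
    return HarmonizedPair(out, audit)
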