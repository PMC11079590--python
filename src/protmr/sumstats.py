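"""GWAS summary-statistic containers, I/O and allele harmonization.

Two-sample Mendelian randomization works entirely from published GWAS
summary statistics: per-variant effect sizes (``beta``), standard errors,
effect-allele frequencies and p-values for an exposure and an outcome
measured in non-overlapping samples.  Before any causal estimator can be
applied, the two sets of statistics have to be *harmonized* so that both
betas refer to the same effect allele on the same strand.  This module
provides

* :class:`VariantAssociation` / :class:`SummaryStats` — validated
  per-variant records for a single trait,
* :func:`read_sumstats` / :func:`write_sumstats` — round-trip-safe
  delimited-text I/O with a flexible column map,
* :func:`harmonize` — the allele truth table (orientation swap, strand
  flip, palindromic-ambiguity drop) producing :class:`HarmonizedPairs`,
  the input of every MR estimator downstream.

Coordinates are 1-based and fully closed, following GWAS summary-file
convention.  The canonical on-disk dialect is a tab-separated table with
the header ``variant_id chrom pos effect_allele other_allele eaf beta se
pval n``; reals are serialized with 12 significant digits so that
``read(write(ss))`` is an identity to that precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitType",
    "TraitInfo",
    "VariantAssociation",
    "SummaryStats",
    "HarmonizedPairs",
    "SumstatsError",
    "ConfigurationError",
    "InputError",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "CANONICAL_COLUMNS",
]

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = (frozenset("AT"), frozenset("CG"))

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


class SumstatsError(ValueError):
    """Base class for summary-statistics input problems."""


class ConfigurationError(SumstatsError):
    """A column map or configuration value is unusable."""


class InputError(SumstatsError):
    """The data themselves violate an invariant."""


class TraitType(str, Enum):
    quantitative = "quantitative"
    binary = "binary"


@dataclass(frozen=True)
class TraitInfo:
    """Metadata for one trait (study) behind a summary-statistics table.

    For binary traits ``n_cases`` must be given; for quantitative traits
    ``sd_y`` (the phenotype SD on the analysis scale) may be given and is
    used e.g. by the colocalization prior.
    """

    trait_id: str
    trait_type: TraitType = TraitType.quantitative
    n_total: int = 0
    n_cases: int | None = None
    sd_y: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trait_type", TraitType(self.trait_type))
        if self.trait_type is TraitType.binary:
            if self.n_cases is None or not (0 < self.n_cases < self.n_total):
                raise InputError(
                    f"binary trait {self.trait_id!r} needs 0 < n_cases < n_total"
                )
        if self.sd_y is not None and self.sd_y <= 0:
            raise InputError(f"trait {self.trait_id!r}: sd_y must be positive")

    @property
    def case_fraction(self) -> float | None:
        if self.trait_type is TraitType.binary:
            return self.n_cases / self.n_total
        return None


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association record for one trait.

    ``beta`` is the per-allele effect of ``effect_allele``: a difference in
    SD units for quantitative traits, a log odds ratio for binary traits.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        reason = _row_problem(
            self.effect_allele,
            self.other_allele,
            self.eaf,
            self.se,
            self.pval,
            self.pos,
            self.n,
        )
        if reason:
            raise InputError(f"variant {self.variant_id!r}: {reason}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC


def _row_problem(ea, oa, eaf, se, pval, pos, n) -> str | None:
    if ea not in NUCLEOTIDES or oa not in NUCLEOTIDES:
        return f"alleles must be single nucleotides, got {ea!r}/{oa!r}"
    if ea == oa:
        return "effect and other allele are identical"
    if not (0.0 < eaf < 1.0):
        return f"eaf {eaf} outside (0, 1)"
    if not se > 0.0:
        return f"se {se} not positive"
    if not (0.0 < pval <= 1.0):
        return f"pval {pval} outside (0, 1]"
    if pos < 1:
        return f"pos {pos} < 1"
    if n < 1:
        return f"n {n} < 1"
    return None


def zp_consistent(z: float, pval: float, rel_tol: float = 0.10) -> bool:
    """Whether |beta/se| agrees with the two-sided normal p-value.

    The implied |z| is recovered from the p-value; agreement means the
    observed |z| is within ``rel_tol`` relative of it, with a small
    absolute slack near the null where the relative scale degenerates.
    """
    implied = float(stats.norm.isf(max(pval, 1e-300) / 2.0))
    return abs(abs(z) - implied) <= rel_tol * implied + 0.05


@dataclass
class SummaryStats:
    """A validated set of :class:`VariantAssociation` records for one trait.

    Backed by a pandas DataFrame in canonical column order; ``variant_id``
    is unique.  Constructed via :meth:`from_frame`, :meth:`from_records`
    or :func:`read_sumstats`.
    """

    trait: TraitInfo
    df: pd.DataFrame
    rejected: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_frame(
        cls,
        trait: TraitInfo,
        df: pd.DataFrame,
        *,
        drop_invalid: bool = False,
        check_zp: bool = True,
        strict: bool = False,
    ) -> "SummaryStats":
        df = df.loc[:, CANONICAL_COLUMNS].copy()
        df["variant_id"] = df["variant_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        for col in ("effect_allele", "other_allele"):
            df[col] = df[col].astype(str).str.upper()
        for col in ("eaf", "beta", "se", "pval"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in ("pos", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")

        dup = df["variant_id"].duplicated()
        if dup.any():
            raise InputError(
                f"duplicate variant_id {df.loc[dup, 'variant_id'].iloc[0]!r}"
            )

        reasons = _vector_problems(df)
        if check_zp:
            zp_bad = _zp_inconsistent_mask(df) & reasons.isna()
            if zp_bad.any():
                ids = ", ".join(df.loc[zp_bad, "variant_id"].head(5))
                msg = (
                    f"{int(zp_bad.sum())} row(s) have beta/se inconsistent with "
                    f"pval under a two-sided normal test (e.g. {ids})"
                )
                if strict:
                    reasons = reasons.mask(zp_bad, "beta/se inconsistent with pval")
                else:
                    warnings.warn(msg, stacklevel=3)
        bad = reasons.notna()
        rejected = list(
            zip(df.loc[bad, "variant_id"].tolist(), reasons[bad].tolist())
        )
        if bad.any() and not drop_invalid:
            vid, why = rejected[0]
            raise InputError(f"variant {vid!r}: {why}")
        df = df.loc[~bad].reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        df["n"] = df["n"].astype(np.int64)
        return cls(trait=trait, df=df, rejected=rejected)

    @classmethod
    def from_records(
        cls, trait: TraitInfo, records: Iterable[VariantAssociation]
    ) -> "SummaryStats":
        rows = [
            {col: getattr(r, col) for col in CANONICAL_COLUMNS} for r in records
        ]
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return cls.from_frame(trait, df, check_zp=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def get(self, variant_id: str) -> VariantAssociation:
        sub = self.df.loc[self.df["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        row = sub.iloc[0]
        return VariantAssociation(**{c: row[c] for c in CANONICAL_COLUMNS})

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStats":
        keep = self.df["variant_id"].isin(set(variant_ids))
        return SummaryStats(self.trait, self.df.loc[keep].reset_index(drop=True))

    def records(self) -> Iterable[VariantAssociation]:
        for row in self.df.itertuples(index=False):
            yield VariantAssociation(
                *(getattr(row, c) for c in CANONICAL_COLUMNS)
            )


def _vector_problems(df: pd.DataFrame) -> pd.Series:
    """Per-row invariant check; returns a string reason or NaN per row."""
    reasons = pd.Series(pd.NA, index=df.index, dtype="object")

    def flag(mask: pd.Series, why: str) -> None:
        nonlocal reasons
        reasons = reasons.mask(mask & reasons.isna(), why)

    numeric_na = df[["eaf", "beta", "se", "pval", "pos", "n"]].isna().any(axis=1)
    flag(numeric_na, "non-numeric field")
    bad_allele = ~df["effect_allele"].isin(NUCLEOTIDES) | ~df["other_allele"].isin(
        NUCLEOTIDES
    )
    flag(bad_allele, "alleles must be single nucleotide codes")
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    flag(~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf outside (0, 1)")
    flag(~(df["se"] > 0), "se not positive")
    flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0, 1]")
    flag(df["pos"] < 1, "pos < 1")
    flag(df["n"] < 1, "n < 1")
    return reasons


def _zp_inconsistent_mask(df: pd.DataFrame) -> pd.Series:
    with np.errstate(all="ignore"):
        z = np.abs(df["beta"] / df["se"])
        implied = stats.norm.isf(np.clip(df["pval"], 1e-300, 1.0) / 2.0)
        ok = np.abs(z - implied) <= 0.10 * implied + 0.05
    return pd.Series(~ok.to_numpy(dtype=bool), index=df.index) & df["pval"].notna()


def read_sumstats(
    path: str | Path,
    trait: TraitInfo,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str | None = "\t",
    strict: bool = False,
    drop_invalid: bool = True,
) -> SummaryStats:
    """Read a delimited summary-statistics table into :class:`SummaryStats`.

    ``column_map`` maps canonical field names to the file's column names;
    omitted entries default to the canonical names.  Rows violating the
    record invariants are dropped and reported in ``SummaryStats.rejected``
    (or raise, if ``drop_invalid=False``).  A beta/se–pval mismatch under
    the two-sided normal test is a warning by default and a rejection under
    ``strict=True`` (summary files imputed on different panels routinely
    carry rounded p-values).
    """
    path = Path(path)
    engine = "python" if sep is None else "c"
    raw = pd.read_csv(path, sep=sep, engine=engine)
    cmap = {c: c for c in CANONICAL_COLUMNS}
    if column_map:
        cmap.update(column_map)
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing mandatory column(s) {missing}"
        )
    df = raw.rename(columns={v: k for k, v in cmap.items()})
    return SummaryStats.from_frame(
        trait, df, drop_invalid=drop_invalid, strict=strict
    )


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    """Write the canonical tab-separated dialect (12 significant digits)."""
    ss.df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Harmonization


@dataclass
class HarmonizedPairs:
    """Exposure/outcome effects aligned to the exposure's effect allele.

    ``df`` columns: variant_id, beta_exp, se_exp, beta_out, se_out, eaf_exp.
    ``dropped`` lists (variant_id, reason) with reason one of
    ``missing_in_outcome``, ``allele_mismatch``, ``palindromic_ambiguous``.
    """

    df: pd.DataFrame
    exposure_trait: TraitInfo
    outcome_trait: TraitInfo
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    @property
    def beta_exp(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(float)

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        *,
        variant_ids: Sequence[str] | None = None,
        eaf_exp=None,
        exposure_trait: TraitInfo | None = None,
        outcome_trait: TraitInfo | None = None,
    ) -> "HarmonizedPairs":
        beta_exp = np.asarray(beta_exp, float)
        k = beta_exp.size
        if variant_ids is None:
            variant_ids = [f"v{i}" for i in range(k)]
        if eaf_exp is None:
            eaf_exp = np.full(k, 0.5)
        df = pd.DataFrame(
            {
                "variant_id": list(variant_ids),
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, float),
                "beta_out": np.asarray(beta_out, float),
                "se_out": np.asarray(se_out, float),
                "eaf_exp": np.asarray(eaf_exp, float),
            }
        )
        return cls(
            df=df,
            exposure_trait=exposure_trait or TraitInfo("exposure"),
            outcome_trait=outcome_trait or TraitInfo("outcome"),
        )

    def drop_variants(self, variant_ids: Sequence[str]) -> "HarmonizedPairs":
        keep = ~self.df["variant_id"].isin(set(variant_ids))
        return HarmonizedPairs(
            self.df.loc[keep].reset_index(drop=True),
            self.exposure_trait,
            self.outcome_trait,
            list(self.dropped),
        )


def _orient_pair(
    e1: str,
    e2: str,
    o1: str,
    o2: str,
    eaf_exp: float,
    eaf_out: float,
    window: float,
) -> tuple[str, int]:
    """Resolve one exposure/outcome allele pair.

    Returns ``(action, sign)`` where action is ``keep`` (outcome beta kept
    with the given sign), ``palindromic_ambiguous`` or ``allele_mismatch``.
    """
    eset = frozenset((e1, e2))
    if eset in _PALINDROMIC:
        # strand flips are invisible for palindromic pairs: orientation can
        # only be inferred from allele-frequency agreement, and not at all
        # when either frequency sits near 0.5
        if frozenset((o1, o2)) != eset:
            return "allele_mismatch", 0
        if abs(eaf_exp - 0.5) <= window or abs(eaf_out - 0.5) <= window:
            return "palindromic_ambiguous", 0
        eaf_out_aligned = eaf_out if o1 == e1 else 1.0 - eaf_out
        same_side = (eaf_exp - 0.5) * (eaf_out_aligned - 0.5) > 0
        sign = 1 if o1 == e1 else -1
        return "keep", sign if same_side else -sign
    if frozenset((o1, o2)) == eset:
        return "keep", 1 if o1 == e1 else -1
    flipped = (COMPLEMENT[o1], COMPLEMENT[o2])
    if frozenset(flipped) == eset:
        return "keep", 1 if flipped[0] == e1 else -1
    return "allele_mismatch", 0


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedPairs:
    """Align outcome effects to the exposure's effect allele.

    For each exposure variant found in the outcome: identical allele pairs
    are kept (with the outcome beta negated when the orientation is
    swapped); complementary-strand pairs are strand-flipped first;
    palindromic (A/T, C/G) pairs are oriented by allele-frequency agreement
    or dropped as ambiguous when either trait's EAF lies within
    ``0.5 ± palindrome_eaf_window``; anything else is an allele mismatch.
    """
    out_idx = outcome.df.set_index("variant_id")
    rows: list[dict] = []
    dropped: list[tuple[str, str]] = []
    for e in exposure.df.itertuples(index=False):
        vid = e.variant_id
        if vid not in out_idx.index:
            dropped.append((vid, "missing_in_outcome"))
            continue
        o = out_idx.loc[vid]
        action, sign = _orient_pair(
            e.effect_allele,
            e.other_allele,
            str(o["effect_allele"]),
            str(o["other_allele"]),
            float(e.eaf),
            float(o["eaf"]),
            palindrome_eaf_window,
        )
        if action != "keep":
            dropped.append((vid, action))
            continue
        rows.append(
            {
                "variant_id": vid,
                "beta_exp": float(e.beta),
                "se_exp": float(e.se),
                "beta_out": sign * float(o["beta"]),
                "se_out": float(o["se"]),
                "eaf_exp": float(e.eaf),
            }
        )
    if not rows and not dropped:
        raise InputError("exposure and outcome share no variants")
    df = pd.DataFrame(
        rows,
        columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp"],
    )
    if df.empty and all(r == "missing_in_outcome" for _, r in dropped):
        raise InputError("exposure and outcome share no variants")
    return HarmonizedPairs(df, exposure.trait, outcome.trait, dropped)
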