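"""Genetic-instrument selection and instrument-strength metrics.

A variant qualifies as an instrument for an exposure when it is
genome-wide significant (P < 5e-8 by default), common (MAF > 0.01) and
independent of every other selected instrument (LD r² < 0.001 within a
10 Mb window when an LD matrix is available, one variant per 10 Mb
otherwise).  Strength is quantified by the variance explained

    R² = 2β²·EAF(1−EAF) / [2β²·EAF(1−EAF) + 2·SE²·n·EAF(1−EAF)]

and the F statistic F = (n−2)·R²/(1−R²); instruments with F < 10 are
conventionally considered weak and are excluded.  ``select_cis_pqtl``
restricts the search to a window around a gene's transcription start
site before applying the same logic, for cis-pQTL analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from .sumstats import InputError, SummaryStats, VariantAssociation

__all__ = [
    "LDMatrix",
    "Instrument",
    "InstrumentSet",
    "EmptyInstrumentSetError",
    "variance_explained",
    "f_statistic",
    "select_instruments",
    "select_cis_pqtl",
]

WEAK_F_THRESHOLD = 10.0


class EmptyInstrumentSetError(InputError):
    """No variant survived instrument filtering."""


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, signed) for a set of variants."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise InputError("LD matrix shape does not match variant_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise InputError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise InputError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise InputError("LD correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self, a: str, b: str) -> float:
        """r² between two variants; 0 when either is absent from the matrix."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib] ** 2)

    @classmethod
    def from_pairs_tsv(cls, path: str | Path) -> "LDMatrix":
        """Build from a TSV of (id_a, id_b, r) rows; absent pairs are r=0."""
        df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
        ids = sorted(set(df["id_a"]) | set(df["id_b"]))
        idx = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        for row in df.itertuples(index=False):
            i, j = idx[row.id_a], idx[row.id_b]
            r[i, j] = r[j, i] = float(row.r)
        return cls(ids, r)


def variance_explained(beta: float, eaf: float, se: float, n: int) -> float:
    """Proportion of trait variance explained by one variant (R²)."""
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"eaf {eaf} outside (0, 1)")
    if se <= 0:
        raise ValueError("se must be positive")
    het = 2.0 * eaf * (1.0 - eaf)
    num = beta * beta * het
    den = num + se * se * n * het
    return num / den


def f_statistic(r2: float, n: int) -> float:
    """Instrument F statistic, F = (n−2)·R²/(1−R²)."""
    if not (0.0 < r2 < 1.0):
        raise ValueError(f"r2 {r2} outside (0, 1)")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return (n - 2) * r2 / (1.0 - r2)


@dataclass(frozen=True)
class Instrument:
    assoc: VariantAssociation
    r2: float
    f_stat: float

    @property
    def variant_id(self) -> str:
        return self.assoc.variant_id


@dataclass
class InstrumentSet:
    instruments: list[Instrument]
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": i.variant_id,
                "chrom": i.assoc.chrom,
                "pos": i.assoc.pos,
                "beta": i.assoc.beta,
                "se": i.assoc.se,
                "pval": i.assoc.pval,
                "eaf": i.assoc.eaf,
                "n": i.assoc.n,
                "r2": i.r2,
                "f_stat": i.f_stat,
            }
            for i in self.instruments
        ]
        return pd.DataFrame(rows)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.selection_log, columns=["variant_id", "action", "reason"]
        )


def select_instruments(
    ss: SummaryStats,
    p_threshold: float = 5e-8,
    maf_min: float = 0.01,
    ld: LDMatrix | None = None,
    ld_r2_max: float = 0.001,
    window_bp: int = 10_000_000,
) -> InstrumentSet:
    """Greedy p-value-ordered instrument selection.

    Candidates must satisfy pval < ``p_threshold`` and MAF > ``maf_min``.
    Pruning walks candidates by ascending p-value (ties by variant_id) and
    accepts a variant only if, among already-accepted variants on the same
    chromosome within ``window_bp``, every LD r² is below ``ld_r2_max``
    (with ``ld``) or there is none at all (distance-only, without ``ld``).
    Accepted variants with F < 10 are dropped as weak; every decision is
    recorded in ``selection_log``.
    """
    log: list[tuple[str, str, str]] = []
    df = ss.df
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    sig = df["pval"] < p_threshold
    common = maf > maf_min
    for vid in df.loc[~sig, "variant_id"]:
        log.append((vid, "dropped", "pval_above_threshold"))
    for vid in df.loc[sig & ~common, "variant_id"]:
        log.append((vid, "dropped", "maf_below_minimum"))
    cand = df.loc[sig & common].sort_values(
        ["pval", "variant_id"], kind="mergesort"
    )

    accepted: list[pd.Series] = []
    for _, row in cand.iterrows():
        conflict = None
        for acc in accepted:
            if acc["chrom"] != row["chrom"]:
                continue
            if abs(int(acc["pos"]) - int(row["pos"])) > window_bp:
                continue
            if ld is None:
                conflict = f"within_{window_bp}bp_of_{acc['variant_id']}"
                break
            if ld.r2(row["variant_id"], acc["variant_id"]) >= ld_r2_max:
                conflict = f"ld_with_{acc['variant_id']}"
                break
        if conflict:
            log.append((row["variant_id"], "dropped", conflict))
        else:
            accepted.append(row)

    instruments: list[Instrument] = []
    for row in accepted:
        assoc = VariantAssociation(
            variant_id=row["variant_id"],
            chrom=row["chrom"],
            pos=int(row["pos"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=int(row["n"]),
        )
        r2 = variance_explained(assoc.beta, assoc.eaf, assoc.se, assoc.n)
        f = f_statistic(r2, assoc.n)
        if f < WEAK_F_THRESHOLD:
            log.append((assoc.variant_id, "dropped", f"weak_instrument_F={f:.3g}"))
            continue
        instruments.append(Instrument(assoc, r2, f))
        log.append((assoc.variant_id, "kept", "selected"))
    if not instruments:
        raise EmptyInstrumentSetError("no variant survived instrument filtering")
    return InstrumentSet(instruments, log)


def select_cis_pqtl(
    ss: SummaryStats,
    gene_chrom: str,
    gene_tss: int,
    window_bp: int = 500_000,
    p_threshold: float = 5e-8,
    **kwargs,
) -> InstrumentSet:
    """Select instruments among variants within ±``window_bp`` of a TSS.

    The window is closed: a variant exactly ``window_bp`` from the TSS is
    inside.  Remaining logic is :func:`select_instruments`.
    """
    df = ss.df
    cis = (df["chrom"] == str(gene_chrom)) & (
        (df["pos"] - gene_tss).abs() <= window_bp
    )
    if not cis.any():
        raise EmptyInstrumentSetError(
            f"no variant within {window_bp} bp of {gene_chrom}:{gene_tss}"
        )
    sub = SummaryStats(ss.trait, df.loc[cis].reset_index(drop=True))
    return select_instruments(sub, p_threshold=p_threshold, **kwargs)
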