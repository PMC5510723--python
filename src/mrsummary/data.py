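"""Summarized-data containers, validation and allele harmonization.

The universal estimator input is :class:`SummaryData`: per-variant
beta-coefficients and standard errors for the variant-exposure association
(``bx``, ``bxse``) and the variant-outcome association (``by``, ``byse``),
optionally decorated with variant identifiers, effect/other alleles, the
effect-allele frequency and a between-variant correlation (LD) matrix.

Estimators accept bare betas; the harmonization operations
(:func:`align_alleles`, :func:`flag_palindromic`,
:func:`orient_to_exposure_increasing`) require allele information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CorrelationMatrixError,
    DataStructureError,
    HarmonizationError,
    StandardErrorError,
)

__all__ = [
    "SummaryData",
    "CorrelationMatrix",
    "HarmonizationResult",
    "validate_summary_data",
    "align_alleles",
    "flag_palindromic",
    "orient_to_exposure_increasing",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: symmetry tolerance for correlation matrices
_SYM_TOL = 1e-10
#: smallest admissible eigenvalue (matrices estimated from finite reference
#: panels can be very slightly indefinite)
_PSD_TOL = -1e-8


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric between-variant correlation matrix, row order = variant order.

    Entries are correlations in [-1, 1] with unit diagonal; the matrix must be
    positive semi-definite up to a small tolerance.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise CorrelationMatrixError(
                f"correlation matrix must be square, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise CorrelationMatrixError("correlation matrix has non-finite entries")
        if np.max(np.abs(v - v.T)) > _SYM_TOL:
            raise CorrelationMatrixError(
                "correlation matrix is asymmetric beyond tolerance"
            )
        if not np.allclose(np.diag(v), 1.0, rtol=0, atol=_SYM_TOL):
            raise CorrelationMatrixError("correlation matrix diagonal must be 1")
        if np.max(np.abs(v)) > 1.0 + _SYM_TOL:
            raise CorrelationMatrixError("correlations must lie in [-1, 1]")
        w = np.linalg.eigvalsh((v + v.T) / 2.0)
        if w.min() < _PSD_TOL:
            raise CorrelationMatrixError(
                f"correlation matrix is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g})"
            )

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SummaryData:
    """Per-variant summarized association data for a two-sample MR analysis.

    Parameters
    ----------
    bx, bxse
        Variant-exposure association betas and their standard errors.
    by, byse
        Variant-outcome association betas (log odds ratios for a binary
        outcome) and their standard errors.
    variant_ids
        Optional unique variant labels (e.g. rsids).
    effect_allele, other_allele
        Optional per-variant allele labels; ``bx``/``by``/``eaf`` refer to
        ``effect_allele``.
    eaf
        Optional effect-allele frequency in (0, 1).
    correlation
        Optional between-variant correlation matrix matching variant order.
    """

    bx: np.ndarray
    bxse: np.ndarray
    by: np.ndarray
    byse: np.ndarray
    variant_ids: Optional[tuple] = None
    effect_allele: Optional[tuple] = None
    other_allele: Optional[tuple] = None
    eaf: Optional[np.ndarray] = None
    correlation: Optional[CorrelationMatrix] = None

    def __post_init__(self):
        for name in ("bx", "bxse", "by", "byse"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, v)
        if self.eaf is not None:
            object.__setattr__(
                self, "eaf", np.atleast_1d(np.asarray(self.eaf, dtype=float))
            )
        for name in ("variant_ids", "effect_allele", "other_allele"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, tuple(v))

    @property
    def n_variants(self) -> int:
        return self.bx.shape[0]

    def __len__(self) -> int:
        return self.n_variants

    def labels(self) -> list[str]:
        """Variant labels, synthesizing ``snp_1..snp_J`` when ids are absent."""
        if self.variant_ids is not None:
            return list(self.variant_ids)
        return [f"snp_{j + 1}" for j in range(self.n_variants)]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per variant) of the numeric fields."""
        d = {
            "snp": self.labels(),
            "bx": self.bx,
            "bxse": self.bxse,
            "by": self.by,
            "byse": self.byse,
        }
        if self.effect_allele is not None:
            d["effect_allele"] = list(self.effect_allele)
        if self.other_allele is not None:
            d["other_allele"] = list(self.other_allele)
        if self.eaf is not None:
            d["eaf"] = self.eaf
        return pd.DataFrame(d)


def validate_summary_data(data: SummaryData) -> SummaryData:
    """Check all :class:`SummaryData` invariants; return the data unchanged.

    Raises
    ------
    DataStructureError
        Vector length mismatch (the message names the offending field) or
        duplicate variant identifiers.
    StandardErrorError
        A non-positive or non-finite standard error (message carries the
        variant index).
    CorrelationMatrixError
        Correlation matrix of the wrong dimension.
    """
    j = data.bx.shape[0]
    if j < 1:
        raise DataStructureError("at least one variant is required")
    for name in ("bxse", "by", "byse"):
        v = getattr(data, name)
        if v.shape[0] != j:
            raise DataStructureError(
                f"length of {name} ({v.shape[0]}) does not match bx ({j})"
            )
    for name in ("bx", "by"):
        v = getattr(data, name)
        if not np.all(np.isfinite(v)):
            idx = int(np.flatnonzero(~np.isfinite(v))[0])
            raise DataStructureError(f"{name} is non-finite at variant index {idx}")
    for name in ("bxse", "byse"):
        v = getattr(data, name)
        bad = ~(np.isfinite(v) & (v > 0))
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise StandardErrorError(
                f"{name} must be strictly positive and finite; "
                f"offending variant index {idx} (value {v[idx]!r})"
            )
    for name in ("variant_ids", "effect_allele", "other_allele"):
        v = getattr(data, name)
        if v is not None and len(v) != j:
            raise DataStructureError(f"length of {name} ({len(v)}) does not match bx ({j})")
    if data.variant_ids is not None and len(set(data.variant_ids)) != j:
        raise DataStructureError("variant_ids must be unique")
    if data.eaf is not None:
        if data.eaf.shape[0] != j:
            raise DataStructureError(
                f"length of eaf ({data.eaf.shape[0]}) does not match bx ({j})"
            )
        if np.any((data.eaf <= 0) | (data.eaf >= 1)):
            raise DataStructureError("eaf must lie strictly in (0, 1)")
    if data.correlation is not None and data.correlation.dim != j:
        raise CorrelationMatrixError(
            f"correlation matrix dimension {data.correlation.dim} "
            f"does not match the number of variants {j}"
        )
    return data


def flag_palindromic(data: SummaryData) -> list:
    """Flag palindromic variants (A/T or C/G allele pairs).

    A palindromic variant reads the same on both strands, so its orientation
    cannot be resolved from allele labels alone. Returns one entry per
    variant: ``True`` (palindromic), ``False`` (not), or ``None`` when the
    allele pair is missing or unrecognized (indeterminate — deliberately not
    reported as ``False``).
    """
    j = data.n_variants
    if data.effect_allele is None or data.other_allele is None:
        return [None] * j
    flags: list = []
    for ea, oa in zip(data.effect_allele, data.other_allele):
        if ea is None or oa is None:
            flags.append(None)
            continue
        ea, oa = str(ea).upper(), str(oa).upper()
        if ea not in _COMPLEMENT or oa not in _COMPLEMENT:
            flags.append(None)
        else:
            flags.append({ea, oa} in ({"A", "T"}, {"C", "G"}))
    return flags


def orient_to_exposure_increasing(data: SummaryData) -> SummaryData:
    """Re-orient every variant to its exposure-increasing allele.

    For each variant with ``bx < 0``, both ``bx`` and ``by`` are negated
    (standard errors are unchanged), the effect-allele frequency is
    complemented, the effect/other allele labels are swapped, and the
    correlation matrix is sign-adjusted consistently
    (``rho'_ij = s_i s_j rho_ij``). Variants with ``bx == 0`` exactly are left
    unchanged: no exposure-increasing allele is defined for them.

    The MR-Egger estimator applies this orientation internally; the
    per-variant ratio ``by/bx`` is invariant under it.
    """
    s = np.where(data.bx < 0, -1.0, 1.0)
    if np.all(s > 0):
        return data
    kwargs: dict = {"bx": data.bx * s, "by": data.by * s}
    if data.eaf is not None:
        kwargs["eaf"] = np.where(s < 0, 1.0 - data.eaf, data.eaf)
    if data.effect_allele is not None and data.other_allele is not None:
        ea = [o if si < 0 else e
              for e, o, si in zip(data.effect_allele, data.other_allele, s)]
        oa = [e if si < 0 else o
              for e, o, si in zip(data.effect_allele, data.other_allele, s)]
        kwargs["effect_allele"] = tuple(ea)
        kwargs["other_allele"] = tuple(oa)
    if data.correlation is not None:
        kwargs["correlation"] = CorrelationMatrix(
            data.correlation.values * np.outer(s, s)
        )
    return replace(data, **kwargs)


@dataclass
class HarmonizationResult:
    """Outcome of :func:`align_alleles`.

    ``data`` holds the harmonized variants; ``dropped`` records the variants
    that could not be reconciled (as ``(variant_id, reason)`` pairs);
    ``strand_flipped`` lists variants that were matched only after
    reverse-complementing the outcome alleles.
    """

    data: SummaryData
    dropped: list = field(default_factory=list)
    strand_flipped: list = field(default_factory=list)


def _records_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(records).copy()
    required = {"snp", "beta", "se", "effect_allele", "other_allele"}
    missing = required - set(df.columns)
    if missing:
        raise HarmonizationError(
            f"association records lack required columns: {sorted(missing)}"
        )
    df["snp"] = df["snp"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    return df


def align_alleles(
    exposure_records,
    outcome_records,
    allow_strand_flip: bool = False,
) -> HarmonizationResult:
    """Harmonize exposure and outcome associations to the same effect allele.

    Both inputs are tables (anything :class:`pandas.DataFrame` accepts) with
    columns ``snp, beta, se, effect_allele, other_allele`` and optional
    ``eaf``. For each variant present on both sides:

    * identical effect/other pairs — outcome beta kept as reported;
    * swapped effect/other pairs — outcome beta sign-flipped (and the
      outcome eaf complemented, though the returned ``eaf`` is the exposure
      side's when available);
    * with ``allow_strand_flip``, non-palindromic variants are additionally
      compared after reverse-complementing the outcome alleles; palindromic
      (A/T, C/G) variants are never strand-flipped, because complementation
      maps their allele pair onto itself and any match would be arbitrary;
    * anything else is irreconcilable: the variant is dropped and reported.

    Raises
    ------
    HarmonizationError
        If the two record sets share no variants.
    """
    exp = _records_frame(exposure_records)
    out = _records_frame(outcome_records)
    if exp["snp"].duplicated().any() or out["snp"].duplicated().any():
        raise HarmonizationError("duplicate variant ids within a record set")
    out = out.set_index("snp")
    shared = [s for s in exp["snp"] if s in out.index]
    if not shared:
        raise HarmonizationError("exposure and outcome records share no variants")

    exp = exp.set_index("snp")
    keep, dropped, flipped = [], [], []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        palindromic = {ea_e, oa_e} in ({"A", "T"}, {"C", "G"})
        sign, via_strand = None, False
        if (ea_o, oa_o) == (ea_e, oa_e):
            sign = 1.0
        elif (ea_o, oa_o) == (oa_e, ea_e):
            sign = -1.0
        elif allow_strand_flip and not palindromic:
            rc = (_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o))
            if rc == (ea_e, oa_e):
                sign, via_strand = 1.0, True
            elif rc == (oa_e, ea_e):
                sign, via_strand = -1.0, True
        if sign is None:
            dropped.append(
                (snp, f"irreconcilable alleles {ea_e}/{oa_e} vs {ea_o}/{oa_o}")
            )
            continue
        if via_strand:
            flipped.append(snp)
        keep.append(
            {
                "snp": snp,
                "bx": float(e["beta"]),
                "bxse": float(e["se"]),
                "by": sign * float(o["beta"]),
                "byse": float(o["se"]),
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "eaf": float(e["eaf"]) if "eaf" in e.index and pd.notna(e.get("eaf")) else np.nan,
            }
        )
    if not keep:
        raise HarmonizationError(
            "no variant could be harmonized; all allele pairs irreconcilable"
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} variant(s) dropped during allele harmonization: "
            + ", ".join(s for s, _ in dropped),
            stacklevel=2,
        )
    tab = pd.DataFrame(keep)
    eaf = tab["eaf"].to_numpy()
    data = SummaryData(
        bx=tab["bx"].to_numpy(),
        bxse=tab["bxse"].to_numpy(),
        by=tab["by"].to_numpy(),
        byse=tab["byse"].to_numpy(),
        variant_ids=tuple(tab["snp"]),
        effect_allele=tuple(tab["effect_allele"]),
        other_allele=tuple(tab["other_allele"]),
        eaf=None if np.isnan(eaf).all() else eaf,
    )
    return HarmonizationResult(
        data=validate_summary_data(data), dropped=dropped, strand_flipped=flipped
    )
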