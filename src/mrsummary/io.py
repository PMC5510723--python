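"""Delimited-text input/output and the association-extraction workflow.

File formats (comma-delimited, header row, UTF-8, '.' decimal):

* **summary CSV** — one row per variant with columns
  ``snp, bx, bxse, by, byse`` and optional
  ``effect_allele, other_allele, eaf``;
* **correlation CSV** — a square matrix with variant ids as both the first
  column and the header row;
* **association CSV** — a long table of per-variant association records in
  the style of a PhenoScanner export, one row per
  (variant, trait, study, ancestry) with optional proxy annotation. The
  column schema is this package's own (documented on
  :class:`ASSOCIATION_COLUMNS`); database exports need a one-off rename to
  match it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import (
    CorrelationMatrix,
    HarmonizationResult,
    SummaryData,
    align_alleles,
    validate_summary_data,
)
from .exceptions import (
    AmbiguityError,
    CorrelationMatrixError,
    SchemaError,
    SelectionError,
)

__all__ = [
    "read_summary_csv",
    "write_summary_csv",
    "read_correlation_matrix",
    "read_association_csv",
    "extract_pheno_csv",
    "ASSOCIATION_COLUMNS",
]

_MANDATORY = ["snp", "bx", "bxse", "by", "byse"]
_OPTIONAL = ["effect_allele", "other_allele", "eaf"]

#: column schema of the association CSV consumed by :func:`extract_pheno_csv`.
#: ``proxy_rsid``/``proxy_r2`` are set on rows that report a proxy variant's
#: association on behalf of the index variant named in ``rsid``.
ASSOCIATION_COLUMNS = [
    "rsid", "trait", "pmid", "ancestry", "beta", "se",
    "effect_allele", "other_allele", "eaf", "proxy_rsid", "proxy_r2",
]


def read_summary_csv(path) -> SummaryData:
    """Read a summary CSV into a validated :class:`SummaryData`.

    Row order is preserved. Raises :class:`SchemaError` for a missing
    mandatory column or a non-numeric cell (the message carries the 1-based
    data row number).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"summary CSV {path} lacks mandatory column(s): {missing}")
    numeric = {}
    for col in ["bx", "bxse", "by", "byse"] + (["eaf"] if "eaf" in df.columns else []):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at data row {row}"
            )
        if parsed.isna().any() and col != "eaf":
            row = int(parsed.isna().idxmax()) + 1
            raise SchemaError(f"missing value in column {col!r} at data row {row}")
        numeric[col] = parsed.to_numpy(dtype=float)
    kwargs = dict(
        bx=numeric["bx"], bxse=numeric["bxse"],
        by=numeric["by"], byse=numeric["byse"],
        variant_ids=tuple(df["snp"].astype(str)),
    )
    if "effect_allele" in df.columns and "other_allele" in df.columns:
        kwargs["effect_allele"] = tuple(df["effect_allele"].astype(str).str.upper())
        kwargs["other_allele"] = tuple(df["other_allele"].astype(str).str.upper())
    if "eaf" in df.columns and not np.isnan(numeric["eaf"]).all():
        kwargs["eaf"] = numeric["eaf"]
    return validate_summary_data(SummaryData(**kwargs))


def write_summary_csv(data: SummaryData, path) -> None:
    """Write a :class:`SummaryData` as a summary CSV (inverse of read)."""
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_correlation_matrix(path, variant_ids) -> CorrelationMatrix:
    """Read a labelled square correlation matrix and reorder to variant_ids.

    The first column and the header carry variant labels; the matrix is
    re-indexed to ``variant_ids`` so downstream row/column order matches the
    :class:`SummaryData` variant order.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    wanted = [str(v) for v in variant_ids]
    absent = [v for v in wanted if v not in df.index or v not in df.columns]
    if absent:
        raise CorrelationMatrixError(
            f"correlation matrix {path} lacks variant(s): {absent}"
        )
    sub = df.loc[wanted, wanted].to_numpy(dtype=float)
    return CorrelationMatrix(values=sub)


def read_association_csv(path) -> pd.DataFrame:
    """Read an association CSV, checking the column schema."""
    df = pd.read_csv(path)
    missing = [c for c in ASSOCIATION_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise SchemaError(f"association CSV {path} lacks column(s): {missing}")
    for col in ("eaf", "proxy_rsid", "proxy_r2"):
        if col not in df.columns:
            df[col] = np.nan
    has_r2 = df["proxy_r2"].notna()
    has_proxy = df["proxy_rsid"].notna()
    if (has_r2 != has_proxy).any():
        raise SchemaError(
            "proxy_r2 must be present exactly when proxy_rsid is present"
        )
    if ((df["proxy_r2"] < 0) | (df["proxy_r2"] > 1)).any():
        raise SchemaError("proxy_r2 must lie in [0, 1]")
    if (df.loc[df["beta"].notna(), "se"] <= 0).any():
        raise SchemaError("se must be positive wherever beta is present")
    return df


def _select_side(
    records: pd.DataFrame, trait: str, pmid: int, ancestry: str, label: str
) -> pd.DataFrame:
    side = records[
        (records["trait"] == trait)
        & (records["pmid"] == pmid)
        & (records["ancestry"] == ancestry)
    ]
    if side.empty:
        raise SelectionError(
            f"no {label} association records match "
            f"(trait={trait!r}, pmid={pmid}, ancestry={ancestry!r})"
        )
    return side


def _resolve_side(
    side: pd.DataFrame, wanted: list, rsq_proxy: float, label: str
) -> tuple[pd.DataFrame, list]:
    """Pick a direct record per wanted variant, else the best proxy record."""
    rows, report = [], []
    for snp in wanted:
        mine = side[side["rsid"] == snp]
        direct = mine[mine["proxy_rsid"].isna()]
        if len(direct) > 1:
            if direct.duplicated(
                subset=["beta", "se", "effect_allele", "other_allele"], keep=False
            ).all():
                direct = direct.iloc[:1]
            else:
                raise AmbiguityError(
                    f"conflicting duplicate {label} records for variant {snp}"
                )
        if len(direct) == 1:
            rows.append((snp, direct.iloc[0], None))
            continue
        proxies = mine[mine["proxy_rsid"].notna() & (mine["proxy_r2"] >= rsq_proxy)]
        if proxies.empty:
            report.append((snp, f"no {label} association and no proxy with "
                                f"r^2 >= {rsq_proxy}"))
            continue
        # highest r^2 wins; ties broken by lexicographically smallest rsid
        proxies = proxies.sort_values(
            ["proxy_r2", "proxy_rsid"], ascending=[False, True]
        )
        best = proxies.iloc[0]
        rows.append((snp, best, (best["proxy_rsid"], float(best["proxy_r2"]))))
    return rows, report


def extract_pheno_csv(
    records: pd.DataFrame,
    exposure: str,
    pmid_e: int,
    ancestry_e: str,
    outcome: str,
    pmid_o: int,
    ancestry_o: str,
    rsq_proxy: float = 0.6,
    snps="all",
) -> HarmonizationResult:
    """Build a harmonized :class:`SummaryData` from an association table.

    Selects the exposure associations matching
    ``(exposure, pmid_e, ancestry_e)`` and the outcome associations matching
    ``(outcome, pmid_o, ancestry_o)``. For any requested variant missing an
    association on one side, the best available proxy with
    ``proxy_r2 >= rsq_proxy`` is substituted (highest r^2 wins; ties go to
    the lexicographically smallest proxy rsid). Variants with no qualifying
    record on either side are dropped and reported. Alleles are then aligned
    to the exposure effect allele via :func:`~mrsummary.data.align_alleles`
    — proxy records carry the proxy's own alleles and betas, so sign
    handling is delegated to the harmonization step.

    ``snps`` is either ``"all"`` (every variant with an exposure-side
    record) or an explicit list of index rsids. Returns a
    :class:`HarmonizationResult`; its ``data`` always passes validation and
    its ``dropped`` list merges proxy-resolution and harmonization drops.
    """
    if not 0 <= rsq_proxy <= 1:
        raise ValueError(f"rsq_proxy must lie in [0, 1], got {rsq_proxy}")
    exp_side = _select_side(records, exposure, pmid_e, ancestry_e, "exposure")
    out_side = _select_side(records, outcome, pmid_o, ancestry_o, "outcome")
    if snps == "all":
        wanted = list(dict.fromkeys(exp_side["rsid"].astype(str)))
    else:
        wanted = [str(s) for s in snps]
    exp_rows, exp_report = _resolve_side(exp_side, wanted, rsq_proxy, "exposure")
    resolved = [snp for snp, _, _ in exp_rows]
    out_rows, out_report = _resolve_side(out_side, resolved, rsq_proxy, "outcome")
    out_by_snp = {snp: (rec, proxy) for snp, rec, proxy in out_rows}

    def _side_frame(rows, out=False):
        frame = []
        for snp, rec, proxy in rows:
            if out and snp not in out_by_snp:
                continue
            frame.append(
                {
                    "snp": snp,
                    "beta": float(rec["beta"]),
                    "se": float(rec["se"]),
                    "effect_allele": str(rec["effect_allele"]).upper(),
                    "other_allele": str(rec["other_allele"]).upper(),
                    "eaf": float(rec["eaf"]) if pd.notna(rec["eaf"]) else np.nan,
                }
            )
        return pd.DataFrame(frame)

    exp_frame = _side_frame(
        [(s, r, p) for s, r, p in exp_rows if s in out_by_snp]
    )
    out_frame = _side_frame(out_rows)
    if exp_frame.empty:
        raise SelectionError(
            "no variant has usable associations on both sides "
            f"(dropped: {exp_report + out_report})"
        )
    result = align_alleles(exp_frame, out_frame)
    result.dropped = exp_report + out_report + result.dropped
    proxies_used = {
        snp: proxy for snp, _, proxy in exp_rows + out_rows if proxy is not None
    }
    if proxies_used:
        warnings.warn(
            "proxy variants substituted: "
            + ", ".join(f"{k} -> {v[0]} (r^2={v[1]:.2f})"
                        for k, v in sorted(proxies_used.items())),
            stacklevel=2,
        )
    return result
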