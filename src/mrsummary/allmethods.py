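"""Run several estimators at once and tabulate them for comparison.

Reporting all of the IVW, MR-Egger and median-based estimates side by side
is the recommended practice when multiple variants are available: the
methods rest on different assumptions, and disagreement between them flags
violations of the instrumental-variable assumptions.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import SummaryData, validate_summary_data
from .estimators import EstimatorOptions, MREstimate, mr_egger, mr_ivw
from .exceptions import MRError
from .maxlik import mr_maxlik
from .median import BootstrapConfig, mr_median

__all__ = ["MethodTable", "mr_all", "MAIN_METHODS"]

TABLE_COLUMNS = ["method", "estimate", "std_error", "ci_lower", "ci_upper", "p_value"]

#: the four-method comparison reported by the default ("main") selection
MAIN_METHODS = ("Simple median", "Weighted median", "IVW", "MR-Egger")


@dataclass
class MethodTable:
    """Estimates from several methods, one row per fitted parameter.

    MR-Egger contributes two rows (slope, then ``"(intercept)"``).
    ``diagnostics`` records methods that could not be run (their rows carry
    NaN cells). ``to_tsv``/``from_tsv`` round-trip the numeric table.
    """

    table: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    def to_tsv(self, path=None) -> str | None:
        text = self.table.to_csv(sep="\t", index=False, float_format="%.17g")
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_tsv(cls, source) -> "MethodTable":
        if isinstance(source, str) and "\t" in source:
            source = _io.StringIO(source)
        df = pd.read_csv(source, sep="\t")
        return cls(table=df[TABLE_COLUMNS])

    def __str__(self) -> str:
        def fmt(v):
            if isinstance(v, float):
                if np.isnan(v):
                    return "."
                if 0 < abs(v) < 1e-3:
                    return f"{v:.2e}"
                return f"{v:.3g}"
            return str(v)

        return self.table.map(fmt).to_string(index=False)


def _rows_from_estimate(est: MREstimate) -> list[dict]:
    rows = [
        {
            "method": est.method,
            "estimate": est.estimate,
            "std_error": est.std_error,
            "ci_lower": est.ci_lower,
            "ci_upper": est.ci_upper,
            "p_value": est.p_value,
        }
    ]
    if est.intercept is not None:
        ic = est.intercept
        rows.append(
            {
                "method": "(intercept)",
                "estimate": ic.estimate,
                "std_error": ic.std_error,
                "ci_lower": ic.ci_lower,
                "ci_upper": ic.ci_upper,
                "p_value": ic.p_value,
            }
        )
    return rows


def mr_all(
    data: SummaryData,
    selection: str = "main",
    options: EstimatorOptions | None = None,
    bootstrap: BootstrapConfig | None = None,
) -> MethodTable:
    """Estimate with several methods and tabulate the results.

    ``selection="main"`` runs the simple median, weighted median, IVW and
    MR-Egger methods; ``"all"`` additionally runs the penalized and robust
    IVW/MR-Egger variants, the penalized weighted median, and the maximum
    likelihood method. A method that cannot be applied (e.g. MR-Egger with
    fewer than 3 variants) contributes NaN rows and a diagnostic message
    instead of failing the whole table.
    """
    if selection not in ("main", "all"):
        raise ValueError(f"selection must be 'main' or 'all', got {selection!r}")
    options = options or EstimatorOptions()
    bootstrap = bootstrap or BootstrapConfig()
    validate_summary_data(data)

    calls: list[tuple[str, object]] = [
        ("Simple median", lambda: mr_median(data, "simple", options, bootstrap)),
        ("Weighted median", lambda: mr_median(data, "weighted", options, bootstrap)),
        ("IVW", lambda: mr_ivw(data, options)),
        ("MR-Egger", lambda: mr_egger(data, options)),
    ]
    if selection == "all":
        calls += [
            (
                "Penalized weighted median",
                lambda: mr_median(data, "penalized", options, bootstrap),
            ),
            ("Penalized IVW",
             lambda: mr_ivw(data, replace(options, penalized=True))),
            ("Robust IVW",
             lambda: mr_ivw(data, replace(options, robust=True))),
            ("Penalized robust IVW",
             lambda: mr_ivw(data, replace(options, penalized=True, robust=True))),
            ("Penalized MR-Egger",
             lambda: mr_egger(data, replace(options, penalized=True))),
            ("Robust MR-Egger",
             lambda: mr_egger(data, replace(options, robust=True))),
            ("Penalized robust MR-Egger",
             lambda: mr_egger(data, replace(options, penalized=True, robust=True))),
            ("Maximum likelihood", lambda: mr_maxlik(data, options)),
        ]

    rows: list[dict] = []
    diagnostics: dict = {}
    for label, call in calls:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = call()
        except MRError as exc:
            diagnostics[label] = str(exc)
            rows.append(
                {
                    "method": label,
                    "estimate": np.nan,
                    "std_error": np.nan,
                    "ci_lower": np.nan,
                    "ci_upper": np.nan,
                    "p_value": np.nan,
                }
            )
            if label.endswith("MR-Egger"):
                rows.append({"method": "(intercept)", "estimate": np.nan,
                             "std_error": np.nan, "ci_lower": np.nan,
                             "ci_upper": np.nan, "p_value": np.nan})
            continue
        rows.extend(_rows_from_estimate(est))
    return MethodTable(table=pd.DataFrame(rows, columns=TABLE_COLUMNS),
                       diagnostics=diagnostics)
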