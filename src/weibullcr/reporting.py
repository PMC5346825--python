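"""Regression-table rendering: per-cause blocks of coefficient (SE), HR,
95% CI and p-value in the layout survival papers print, plus JSON
serialisation of fit results at full precision."""

from __future__ import annotations

import json

import numpy as np

from .fitting import CauseSpecificFit, hazard_ratio

CAUSE_LABELS_DEFAULT = {
    1: "Death from colorectal cancer",
    2: "Death from other causes",
}

#: Rows of the rendered table: (display label, design column or None for
#: a reference row, group header or None).
_TABLE_ROWS = [
    ("BMI (kg/m2)", "bmi", None),
    ("Age at diagnosis", "age", None),
    (None, None, "Sex"),
    ("Man", None, None),  # reference
    ("Woman", "sex_woman", None),
    (None, None, "Stage"),
    ("Stage I", None, None),  # reference
    ("Stage II", "stage_II", None),
    ("Stage III", "stage_III", None),
    ("Stage IV", "stage_IV", None),
]


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_fit_table(
    fits: list[CauseSpecificFit],
    cause_labels: dict[int, str] | None = None,
) -> str:
    """Render fits as a TSV table: one block per cause, with columns
    Coefficient (SE), HR, 95% CI, P value.  Reference rows show HR 1 and a
    blank coefficient.  Numbers carry three decimals (the JSON export keeps
    full precision)."""
    labels = dict(CAUSE_LABELS_DEFAULT)
    if cause_labels:
        labels.update(cause_labels)
    lines = ["Event\tCovariate\tCoefficient (SE)\tHR\t95% CI\tP value"]
    for fit in fits:
        label = labels.get(fit.cause, f"Cause {fit.cause}")
        if not fit.estimable:
            lines.append(f"{label}\t(not estimable: {fit.message})\t\t\t\t")
            continue
        first = True
        for display, column, header in _TABLE_ROWS:
            event_cell = label if first else ""
            if header is not None:
                lines.append(f"{event_cell}\t{header}\t\t\t\t")
            elif column is None:
                lines.append(f"{event_cell}\t{display}\t\t1\t\t")
            else:
                hr = hazard_ratio(fit, column)
                i = fit.design_columns.index(column)
                coef, se = fit.beta[i], fit.beta_se[i]
                lines.append(
                    f"{event_cell}\t{display}\t{coef:.3f}({se:.3f})\t{hr.hr:.3f}\t"
                    f"({hr.ci_low:.3f}-{hr.ci_high:.3f})\t{_fmt_p(hr.p_value)}"
                )
            first = False
    return "\n".join(lines) + "\n"


def parse_fit_table(text: str) -> list[dict]:
    """Parse a rendered table back into covariate rows (round-trip check)."""
    rows = []
    for line in text.strip().splitlines()[1:]:
        cells = line.split("\t")
        if len(cells) < 6 or not cells[2]:
            continue
        coef_str, se_str = cells[2].rstrip(")").split("(")
        lo, hi = cells[4].strip("()").split("-")
        rows.append(
            {
                "covariate": cells[1],
                "coef": float(coef_str),
                "se": float(se_str),
                "hr": float(cells[3]),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p": cells[5],
            }
        )
    return rows


def fits_to_json(fits: list[CauseSpecificFit]) -> str:
    return json.dumps([f.to_dict() for f in fits], indent=2)


def fits_from_json(text: str) -> list[CauseSpecificFit]:
    out = []
    for d in json.loads(text):
        out.append(
            CauseSpecificFit(
                cause=d["cause"],
                beta=np.asarray(d["beta"]),
                shape=d["shape"],
                covariance=np.asarray(d["covariance"]),
                loglik=d["loglik"],
                converged=d["converged"],
                n_iter=d["n_iter"],
                n_events=d["n_events"],
                estimable=d["estimable"],
                message=d.get("message", ""),
                design_columns=tuple(d["design_columns"]),
            )
        )
    return out
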