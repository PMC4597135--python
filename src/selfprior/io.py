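"""Trial-table CSV reading/writing with strict validation.

Schema: one row per trial with the columns in
:data:`selfprior.synthetic.TRIAL_COLUMNS`.  Skipped trials leave
``point_x`` and ``estimation_time`` empty; all other rows must carry
them.  Unknown columns are preserved.  UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .synthetic import TRIAL_COLUMNS

_REQUIRED = set(TRIAL_COLUMNS)
_NUMERIC = ["target_x", "stop_x", "point_x", "stop_time", "estimation_time"]
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


class TrialTableError(ValueError):
    """Raised on schema violations, naming the offending row when known."""


def _parse_bool(value, line_no: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE and s != "":
        return False
    raise TrialTableError(f"line {line_no}: invalid boolean {value!r} in 'skipped'")


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    Errors report 1-based file line numbers (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise TrialTableError(f"missing mandatory columns: {sorted(missing)}")
    if len(df) == 0:
        raise TrialTableError("trial table contains no rows")
    out = df.copy()
    skipped = [
        _parse_bool(v, i + 2) for i, v in enumerate(df["skipped"].tolist())
    ]
    out["skipped"] = skipped
    for col in _NUMERIC:
        vals = []
        optional = col in ("point_x", "estimation_time")
        for i, raw in enumerate(df[col].tolist()):
            line_no = i + 2
            s = str(raw).strip()
            if s == "" or s.lower() == "nan":
                if optional and skipped[i]:
                    vals.append(np.nan)
                    continue
                raise TrialTableError(
                    f"line {line_no}: missing value in {col!r} on a "
                    f"{'non-skipped' if not skipped[i] else ''} trial".strip()
                )
            try:
                vals.append(float(s))
            except ValueError:
                raise TrialTableError(
                    f"line {line_no}: non-numeric value {raw!r} in {col!r}"
                ) from None
        out[col] = vals
    for col in ("block", "trial_index", "n_sweeps"):
        try:
            out[col] = df[col].astype(int)
        except ValueError:
            bad = next(
                i + 2
                for i, v in enumerate(df[col].tolist())
                if not str(v).strip().lstrip("-").isdigit()
            )
            raise TrialTableError(
                f"line {bad}: non-integer value in {col!r}"
            ) from None
    return out


def write_trials(trials: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trial table CSV (canonical columns first, extras preserved)."""
    extras = [c for c in trials.columns if c not in TRIAL_COLUMNS]
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns] + extras
    trials[cols].to_csv(path, index=False)


def write_json(obj, path: Union[str, Path]) -> None:
    """Deterministic JSON output (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: Union[str, Path]):
    return json.loads(Path(path).read_text())
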