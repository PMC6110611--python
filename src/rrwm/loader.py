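"""Best-effort loader for external trial-level delayed-estimation files.

Published datasets in this area come in loosely standardized delimited
tables with varying column names and units.  :func:`load_trials_any`
sniffs the delimiter, maps common column aliases onto the package's
trial-table schema (subject, set_size, p_probe, error_rad,
condition_tag), converts degree-valued errors to radians when the value
range makes the unit unambiguous, and optionally doubles
180°-periodic orientation errors onto the full circle.  It is a
convenience for exploring archived data and is deliberately permissive;
the rest of the package only guarantees behavior for tables in the
native schema (see :func:`rrwm.fitting.read_trials`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circdist import wrap_angle

__all__ = ["load_trials_any"]

_ALIASES = {
    "subject": ("subject", "subj", "subject_id", "sid", "participant"),
    "set_size": ("set_size", "setsize", "n_items", "n", "ss"),
    "p_probe": ("p_probe", "probe_prob", "probing_probability", "p", "prob"),
    "error_rad": ("error_rad", "error", "err", "response_error", "estimation_error",
                  "error_deg"),
    "condition_tag": ("condition_tag", "condition", "cond", "block"),
}


def _find_column(df: pd.DataFrame, target: str) -> str | None:
    lowered = {c.lower().strip(): c for c in df.columns}
    for alias in _ALIASES[target]:
        if alias in lowered:
            return lowered[alias]
    return None


def load_trials_any(path, orientation_double: bool = False) -> pd.DataFrame:
    """Read a delimited trial table with unknown conventions.

    Errors whose magnitudes exceed pi are assumed to be in degrees and
    are converted.  With ``orientation_double=True``, 180-degree-periodic
    orientation errors are doubled onto the circle (off by default; use
    only for orientation data known to use the half-circle convention).
    Raises ``ValueError`` when no error column can be identified.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    out = pd.DataFrame()
    err_col = _find_column(df, "error_rad")
    if err_col is None:
        raise ValueError(f"could not identify an error column in {path}; "
                         f"found columns {list(df.columns)}")
    err = pd.to_numeric(df[err_col], errors="coerce").to_numpy(float)
    if np.nanmax(np.abs(err)) > np.pi + 1e-9:   # degree-valued errors
        err = np.deg2rad(err)
    if orientation_double:
        err = 2.0 * err
    out["error_rad"] = wrap_angle(err)

    col = _find_column(df, "subject")
    out["subject"] = df[col].astype(str) if col else "S1"
    col = _find_column(df, "set_size")
    out["set_size"] = pd.to_numeric(df[col], errors="coerce").astype(int) if col else 1
    col = _find_column(df, "p_probe")
    if col:
        out["p_probe"] = pd.to_numeric(df[col], errors="coerce")
    else:
        out["p_probe"] = 1.0 / out["set_size"]
    col = _find_column(df, "condition_tag")
    out["condition_tag"] = df[col].astype(str) if col else ""
    return out[["subject", "set_size", "p_probe", "error_rad", "condition_tag"]]
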