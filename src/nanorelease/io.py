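"""Delimited-text readers and writers for release profiles.

The profile table format is plain delimited text (comma by default, tab
accepted) with a required header ``time_days, fraction_released,
temperature_C`` and an optional ``replicate`` column; lines starting with
``#`` are comments.  Temperatures are degC at the interface and converted to
kelvin exactly once, on read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .arrhenius import celsius_to_kelvin
from .fitting import ReleaseProfile

__all__ = ["ProfileParseError", "read_profiles", "write_profiles"]

REQUIRED_COLUMNS = ("time_days", "fraction_released", "temperature_C")


class ProfileParseError(ValueError):
    """Raised for malformed profile tables, with file line numbers."""


def _data_line_numbers(text: str):
    """1-based line numbers of non-comment, non-blank lines (header first)."""
    return [
        i
        for i, line in enumerate(text.splitlines(), start=1)
        if line.strip() and not line.lstrip().startswith("#")
    ]


def read_profiles(path, delimiter: Optional[str] = None) -> List[ReleaseProfile]:
    """Read a profile table, returning one profile per (temperature,
    replicate) group in order of first appearance.

    Raises :class:`ProfileParseError` with the offending file line number for
    out-of-range fractions and non-monotone times.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = _data_line_numbers(text)
    if not lines:
        raise ProfileParseError(f"{path}: no data lines")
    try:
        df = pd.read_csv(
            _io.StringIO(text),
            comment="#",
            sep=delimiter,
            engine="python",
            skip_blank_lines=True,
        )
    except Exception as exc:
        raise ProfileParseError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileParseError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ProfileParseError(f"{path}: table has a header but no rows")
    # map dataframe row ordinal -> file line (header occupies lines[0])
    row_line = lines[1 : 1 + len(df)]

    bad = df["fraction_released"].lt(0) | df["fraction_released"].gt(1.05)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ProfileParseError(
            f"{path}, line {row_line[i]}: fraction_released="
            f"{df['fraction_released'].iloc[i]} outside [0, 1.05]"
        )

    keys = ["temperature_C"] + (["replicate"] if "replicate" in df.columns else [])
    profiles = []
    for key, group in df.groupby(keys, sort=False):
        t = group["time_days"].to_numpy(dtype=float)
        nonmono = np.flatnonzero(np.diff(t) <= 0)
        if nonmono.size:
            i = int(group.index[nonmono[0] + 1])
            raise ProfileParseError(
                f"{path}, line {row_line[i]}: time_days not strictly increasing"
            )
        temp_C = key[0] if isinstance(key, tuple) else key
        label = f"{temp_C:g}C"
        if "replicate" in df.columns:
            label += f"-rep{key[1]}"
        profiles.append(
            ReleaseProfile(
                times=t,
                fractions=group["fraction_released"].to_numpy(dtype=float),
                temperature_K=float(celsius_to_kelvin(temp_C)),
                label=label,
            )
        )
    return profiles


def write_profiles(profiles, path, delimiter: str = ",") -> None:
    """Write profiles to a delimited table (lossless round trip with
    :func:`read_profiles` up to grouping)."""
    frames = []
    for prof in profiles:
        frame = pd.DataFrame(
            {
                "time_days": prof.times,
                "fraction_released": prof.fractions,
                "temperature_C": (
                    prof.temperature_K - 273.15
                    if prof.temperature_K is not None
                    else np.nan
                ),
            }
        )
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=delimiter, index=False)
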