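"""Reading and writing two-group samples as CSV/TSV.

Three layouts are supported:

* ``long`` -- one value column and one group-label column;
* ``wide`` -- two named columns, one per group;
* ``two_file`` -- one single-column file per group.

Lines starting with ``#`` and blank lines are ignored everywhere.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import TwoGroupSample
from .scenarios import ScenarioSpec, sample_scenario

__all__ = ["read_two_group", "write_fixture"]

logger = logging.getLogger(__name__)


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True,
                           float_precision="round_trip", **kw)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty group in {path} (no data rows)") from None


def _numeric(series: pd.Series, where: str) -> np.ndarray:
    values = pd.to_numeric(series, errors="coerce")
    bad = series[values.isna() & series.notna()]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"non-numeric measurement {bad.iloc[0]!r} in {where} (data row {row + 1})"
        )
    out = values.dropna().to_numpy(dtype=float)
    if out.size == 0:
        raise ValueError(f"empty group in {where}")
    return out


def read_two_group(
    source: str | Path | tuple[str | Path, str | Path],
    layout: str = "long",
    value_col: str = "value",
    group_col: str = "group",
    labels: tuple[str, str] | None = None,
) -> TwoGroupSample:
    """Read a two-group sample from file(s).

    ``labels`` names the (non-diseased, diseased) groups: the group
    labels in a ``long`` file, the column names in a ``wide`` file
    (defaults to the value/group column arguments there).  When omitted
    for ``long`` input, the first-seen label is taken as non-diseased --
    a deterministic rule, logged so it can be checked.
    """
    if layout == "two_file":
        if not (isinstance(source, tuple) and len(source) == 2):
            raise ValueError("two_file layout needs a (non_diseased, diseased) path pair")
        x = _numeric(_read_csv(source[0], header=None)[0], str(source[0]))
        y = _numeric(_read_csv(source[1], header=None)[0], str(source[1]))
    elif layout == "wide":
        df = _read_csv(source)
        cols = labels if labels is not None else tuple(df.columns[:2])
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"column {c!r} not found in {source}; have {list(df.columns)}")
        x = _numeric(df[cols[0]], f"{source}:{cols[0]}")
        y = _numeric(df[cols[1]], f"{source}:{cols[1]}")
    elif layout == "long":
        df = _read_csv(source)
        for c in (value_col, group_col):
            if c not in df.columns:
                raise ValueError(f"column {c!r} not found in {source}; have {list(df.columns)}")
        seen = list(dict.fromkeys(df[group_col].astype(str)))
        if len(seen) != 2:
            raise ValueError(
                f"expected exactly 2 group labels in {source}, found {len(seen)}: {seen}"
            )
        if labels is None:
            labels = (seen[0], seen[1])
            logger.info("groups inferred: non-diseased=%r, diseased=%r", *labels)
        missing = set(labels) - set(seen)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not present in {source}; found {seen}")
        g = df[group_col].astype(str)
        x = _numeric(df.loc[g == labels[0], value_col], f"{source} group {labels[0]!r}")
        y = _numeric(df.loc[g == labels[1], value_col], f"{source} group {labels[1]!r}")
    else:
        raise ValueError(f"unknown layout {layout!r}; choose long, wide or two_file")
    sample = TwoGroupSample(x, y)
    logger.info(
        "read m=%d (range %.4g..%.4g), n=%d (range %.4g..%.4g)",
        sample.m, sample.x.min(), sample.x.max(),
        sample.n, sample.y.min(), sample.y.max(),
    )
    return sample


def write_fixture(spec: ScenarioSpec, seed: int, path: str | Path) -> TwoGroupSample:
    """Draw a sample from a scenario and write it as a long-layout CSV.

    The header comment records the scenario (families, parameters, true
    J, seed) so the file is self-describing; given the same spec and
    seed the file is byte-identical.
    """
    sample = sample_scenario(spec, seed)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# synthetic two-group sample: non_diseased={spec.non_diseased.family}"
            f"{spec.non_diseased.params}, diseased={spec.diseased.family}"
            f"{spec.diseased.params}\n"
            f"# true_j={spec.true_j:.6f}, true_cut={spec.true_cut:.6f}, "
            f"m={spec.m}, n={spec.n}, seed={seed}\n"
        )
        fh.write("value,group\n")
        for v in sample.x:
            fh.write(f"{float(v)!r},non_diseased\n")
        for v in sample.y:
            fh.write(f"{float(v)!r},diseased\n")
    return sample
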