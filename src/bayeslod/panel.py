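"""Censored concentration panels: in-memory container and on-disk dialect.

A *panel* holds concentrations of J analytes (here: metals) for a set of
individuals, each labelled with a group (``ASD`` / ``control``) and a
sampling stage (``cord`` blood at birth / ``five_year`` serum).  Every cell
is in exactly one of three observation states:

``observed``
    a positive measured concentration;
``below_limit``
    the instrument reported only that the value lies below its detection
    limit ``c`` (left-censored);
``interval``
    the value was not recorded and is known only to lie in a plausibility
    interval ``[lower, upper)`` (interval-censored missingness).

On-disk dialect (CSV or TSV, UTF-8, header row required): one row per
individual with columns ``id, group, stage, <metal>, <metal>, ...``.  A
metal cell is either a plain number (observed), the token ``<LIMIT`` such
as ``<0.5`` (below the detection limit 0.5; limits may differ between
rows), an empty cell (missing, mapped to the configured default interval
for that metal), or an explicit interval token ``lower:upper`` when the
interval differs from the default.  The default missing interval for a
metal is ``[0, 10 x largest observed value of that metal in the panel]``.
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellStatus",
    "CellObservation",
    "PanelSchema",
    "MetalPanel",
    "load_panel",
    "write_panel",
    "censoring_summary",
]

GROUPS = ("ASD", "control")
STAGES = ("cord", "five_year")

_GROUP_ALIASES = {
    "asd": "ASD",
    "autism": "ASD",
    "aut": "ASD",
    "case": "ASD",
    "control": "control",
    "ctrl": "control",
    "ctr": "control",
}
_STAGE_ALIASES = {
    "cord": "cord",
    "cord_blood": "cord",
    "0": "cord",
    "birth": "cord",
    "five_year": "five_year",
    "5": "five_year",
    "5y": "five_year",
    "five": "five_year",
    "serum": "five_year",
}


class CellStatus(enum.IntEnum):
    OBSERVED = 0
    BELOW_LIMIT = 1
    INTERVAL = 2


@dataclass(frozen=True)
class CellObservation:
    """One analyte measurement for one individual.

    Exactly the fields belonging to the active ``status`` are populated;
    the others are ``None``.
    """

    status: CellStatus
    value: float | None = None
    limit: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        s = self.status
        if s == CellStatus.OBSERVED:
            if self.value is None or not self.value > 0:
                raise ValueError(f"observed cell requires value > 0, got {self.value}")
            if self.limit is not None or self.lower is not None or self.upper is not None:
                raise ValueError("observed cell must only carry a value")
        elif s == CellStatus.BELOW_LIMIT:
            if self.limit is None or not self.limit > 0:
                raise ValueError(f"below_limit cell requires limit > 0, got {self.limit}")
            if self.value is not None or self.lower is not None or self.upper is not None:
                raise ValueError("below_limit cell must only carry a limit")
        elif s == CellStatus.INTERVAL:
            if self.lower is None or self.upper is None:
                raise ValueError("interval cell requires lower and upper")
            if not (0 <= self.lower < self.upper):
                raise ValueError(f"interval requires 0 <= lower < upper, got [{self.lower}, {self.upper}]")
            if self.value is not None or self.limit is not None:
                raise ValueError("interval cell must only carry bounds")
        else:  # pragma: no cover
            raise ValueError(f"unknown status {s!r}")

    # log-scale truncation bounds used by the sampler and likelihood
    def log_bounds(self) -> tuple[float, float]:
        if self.status == CellStatus.OBSERVED:
            v = math.log(self.value)
            return v, v
        if self.status == CellStatus.BELOW_LIMIT:
            return -math.inf, math.log(self.limit)
        lo = -math.inf if self.lower == 0 else math.log(self.lower)
        return lo, math.log(self.upper)


def canonical_group(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValueError(f"unknown group label {label!r} (expected one of {sorted(set(_GROUP_ALIASES))})")
    return _GROUP_ALIASES[key]


def canonical_stage(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _STAGE_ALIASES:
        raise ValueError(f"unknown stage label {label!r} (expected one of {sorted(set(_STAGE_ALIASES))})")
    return _STAGE_ALIASES[key]


@dataclass
class PanelSchema:
    """Column mapping and parsing rules for the on-disk dialect."""

    id_col: str = "id"
    group_col: str = "group"
    stage_col: str = "stage"
    metal_cols: list[str] | None = None  # None: every other column, in file order
    unit: str = ""
    #: per-metal default interval for empty (missing) cells; metals not listed
    #: get [0, 10 x largest observed value of that metal in the panel]
    missing_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    missing_upper_factor: float = 10.0


@dataclass
class MetalPanel:
    """Individuals x metals with per-cell observation status.

    Cell state is stored columnar: ``status`` holds :class:`CellStatus`
    codes and ``value``/``limit``/``lower``/``upper`` hold the fields of
    the active status (NaN elsewhere).
    """

    metals: list[str]
    ids: list[str]
    group: np.ndarray  # (n,) canonical group labels
    stage: np.ndarray  # (n,) canonical stage labels
    status: np.ndarray  # (n, J) int8 CellStatus codes
    value: np.ndarray  # (n, J) float
    limit: np.ndarray  # (n, J) float
    lower: np.ndarray  # (n, J) float
    upper: np.ndarray  # (n, J) float
    unit: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, J = self.status.shape
        if len(self.metals) != J:
            raise ValueError("metal list does not match cell columns")
        if not (len(self.ids) == len(self.group) == len(self.stage) == n):
            raise ValueError("row metadata does not match cell rows")
        if n == 0 or J == 0:
            raise ValueError("panel must contain at least one individual and one metal")
        for g in np.unique(self.group):
            if g not in GROUPS:
                raise ValueError(f"non-canonical group label {g!r}")
        for s in np.unique(self.stage):
            if s not in STAGES:
                raise ValueError(f"non-canonical stage label {s!r}")
        obs = self.status == CellStatus.OBSERVED
        bl = self.status == CellStatus.BELOW_LIMIT
        iv = self.status == CellStatus.INTERVAL
        if np.all(iv):
            raise ValueError("panel carries no information: every cell is an interval")
        if not np.all(self.value[obs] > 0):
            raise ValueError("observed concentrations must be positive")
        if not np.all(self.limit[bl] > 0):
            raise ValueError("detection limits must be positive")
        if iv.any():
            lo, hi = self.lower[iv], self.upper[iv]
            if not (np.all(lo >= 0) and np.all(lo < hi)):
                raise ValueError("interval cells require 0 <= lower < upper")

    # -- basic views ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.status.shape[0]

    @property
    def J(self) -> int:
        return self.status.shape[1]

    def cell(self, i: int, j: int) -> CellObservation:
        s = CellStatus(self.status[i, j])
        if s == CellStatus.OBSERVED:
            return CellObservation(s, value=float(self.value[i, j]))
        if s == CellStatus.BELOW_LIMIT:
            return CellObservation(s, limit=float(self.limit[i, j]))
        return CellObservation(s, lower=float(self.lower[i, j]), upper=float(self.upper[i, j]))

    def row_cells(self, i: int) -> list[CellObservation]:
        return [self.cell(i, j) for j in range(self.J)]

    def subset(self, group: str | None = None, stage: str | None = None,
               drop_index: int | None = None) -> "MetalPanel":
        """Restrict to a group and/or stage; optionally drop one row (LOOCV)."""
        mask = np.ones(self.n, dtype=bool)
        if group is not None:
            mask &= self.group == canonical_group(group)
        if stage is not None:
            mask &= self.stage == canonical_stage(stage)
        idx = np.where(mask)[0]
        if drop_index is not None:
            idx = idx[idx != drop_index]
        if idx.size == 0:
            raise ValueError("subset selects no individuals")
        return MetalPanel(
            metals=list(self.metals),
            ids=[self.ids[i] for i in idx],
            group=self.group[idx].copy(),
            stage=self.stage[idx].copy(),
            status=self.status[idx].copy(),
            value=self.value[idx].copy(),
            limit=self.limit[idx].copy(),
            lower=self.lower[idx].copy(),
            upper=self.upper[idx].copy(),
            unit=self.unit,
            meta=dict(self.meta),
        )

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-cell log-scale (lower, upper) truncation bounds and free mask.

        Observed cells get a degenerate bound at their log-value; censored
        and interval cells get their truncation interval.  ``free`` marks
        the cells the sampler must impute.
        """
        lo = np.full(self.status.shape, -np.inf)
        hi = np.full(self.status.shape, np.inf)
        obs = self.status == CellStatus.OBSERVED
        bl = self.status == CellStatus.BELOW_LIMIT
        iv = self.status == CellStatus.INTERVAL
        logv = np.log(self.value, where=obs, out=np.full(self.status.shape, np.nan))
        lo[obs] = hi[obs] = logv[obs]
        hi[bl] = np.log(self.limit[bl])
        hi[iv] = np.log(self.upper[iv])
        with np.errstate(divide="ignore"):
            lov = self.lower[iv]
            lo[iv] = np.where(lov > 0, np.log(np.where(lov > 0, lov, 1.0)), -np.inf)
        return lo, hi, ~obs


def _default_intervals(observed_max: dict[str, float], limit_max: dict[str, float],
                       schema: PanelSchema) -> dict[str, tuple[float, float]]:
    out = {}
    for metal in set(observed_max) | set(limit_max) | set(schema.missing_intervals):
        if metal in schema.missing_intervals:
            out[metal] = tuple(schema.missing_intervals[metal])
            continue
        ref = observed_max.get(metal)
        if ref is None or not np.isfinite(ref):
            ref = limit_max.get(metal)
        if ref is None or not np.isfinite(ref):
            ref = 1.0
        out[metal] = (0.0, schema.missing_upper_factor * ref)
    return out


def _sep_for(path: str) -> str:
    return "\t" if os.path.splitext(str(path))[1].lower() in (".tsv", ".tab") else ","


def load_panel(path, schema: PanelSchema | None = None) -> MetalPanel:
    """Read a censored concentration panel from a delimited text file.

    Raises
    ------
    ValueError
        for malformed numerics (naming the row and column), negative
        concentrations, or unknown group/stage labels.
    """
    schema = schema or PanelSchema()
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in (schema.id_col, schema.group_col, schema.stage_col):
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    metals = schema.metal_cols or [c for c in raw.columns
                                   if c not in (schema.id_col, schema.group_col, schema.stage_col)]
    if not metals:
        raise ValueError("no metal columns found")
    n, J = len(raw), len(metals)

    status = np.zeros((n, J), dtype=np.int8)
    value = np.full((n, J), np.nan)
    limit = np.full((n, J), np.nan)
    lower = np.full((n, J), np.nan)
    upper = np.full((n, J), np.nan)
    missing: list[tuple[int, int]] = []

    def _num(tok: str, i: int, metal: str) -> float:
        try:
            x = float(tok)
        except ValueError:
            raise ValueError(f"malformed numeric {tok!r} at row {i + 1}, column {metal!r}") from None
        if not np.isfinite(x):
            raise ValueError(f"non-finite value {tok!r} at row {i + 1}, column {metal!r}")
        if x < 0:
            raise ValueError(f"negative concentration {x} at row {i + 1}, column {metal!r}")
        return x

    for j, metal in enumerate(metals):
        col = raw[metal].astype(str)
        for i, tok in enumerate(col):
            tok = tok.strip()
            if tok == "":
                status[i, j] = CellStatus.INTERVAL
                missing.append((i, j))
            elif tok.startswith("<"):
                status[i, j] = CellStatus.BELOW_LIMIT
                lim = _num(tok[1:].strip(), i, metal)
                if lim <= 0:
                    raise ValueError(f"detection limit must be positive at row {i + 1}, column {metal!r}")
                limit[i, j] = lim
            elif ":" in tok:
                a, _, b = tok.partition(":")
                status[i, j] = CellStatus.INTERVAL
                lower[i, j] = _num(a.strip(), i, metal)
                upper[i, j] = _num(b.strip(), i, metal)
            else:
                status[i, j] = CellStatus.OBSERVED
                v = _num(tok, i, metal)
                if v <= 0:
                    raise ValueError(f"observed concentration must be positive at row {i + 1}, column {metal!r}")
                value[i, j] = v

    obs_max = {m: (np.nanmax(value[:, j]) if np.any(status[:, j] == CellStatus.OBSERVED) else np.nan)
               for j, m in enumerate(metals)}
    lim_max = {m: (np.nanmax(limit[:, j]) if np.any(status[:, j] == CellStatus.BELOW_LIMIT) else np.nan)
               for j, m in enumerate(metals)}
    defaults = _default_intervals(obs_max, lim_max, schema)
    for i, j in missing:
        lower[i, j], upper[i, j] = defaults[metals[j]]

    return MetalPanel(
        metals=list(metals),
        ids=[str(x) for x in raw[schema.id_col]],
        group=np.array([canonical_group(g) for g in raw[schema.group_col]], dtype=object),
        stage=np.array([canonical_stage(s) for s in raw[schema.stage_col]], dtype=object),
        status=status, value=value, limit=limit, lower=lower, upper=upper,
        unit=schema.unit,
        meta={"source": str(path)},
    )


def write_panel(panel: MetalPanel, path, schema: PanelSchema | None = None) -> None:
    """Write a panel back to the on-disk dialect (round-trip exact).

    Interval cells whose bounds equal the schema's default interval for the
    metal are written as empty cells; other intervals use ``lower:upper``.
    """
    schema = schema or PanelSchema()
    obs_max = {m: (np.nanmax(panel.value[:, j])
                   if np.any(panel.status[:, j] == CellStatus.OBSERVED) else np.nan)
               for j, m in enumerate(panel.metals)}
    lim_max = {m: (np.nanmax(panel.limit[:, j])
                   if np.any(panel.status[:, j] == CellStatus.BELOW_LIMIT) else np.nan)
               for j, m in enumerate(panel.metals)}
    defaults = _default_intervals(obs_max, lim_max, schema)

    cols = {schema.id_col: panel.ids,
            schema.group_col: list(panel.group),
            schema.stage_col: list(panel.stage)}
    for j, metal in enumerate(panel.metals):
        toks = []
        for i in range(panel.n):
            s = panel.status[i, j]
            if s == CellStatus.OBSERVED:
                toks.append(repr(float(panel.value[i, j])))
            elif s == CellStatus.BELOW_LIMIT:
                toks.append("<" + repr(float(panel.limit[i, j])))
            else:
                lo, hi = float(panel.lower[i, j]), float(panel.upper[i, j])
                if (lo, hi) == defaults.get(metal, (None, None)):
                    toks.append("")
                else:
                    toks.append(f"{lo!r}:{hi!r}")
        cols[metal] = toks
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False)


def censoring_summary(panel: MetalPanel) -> pd.DataFrame:
    """Per-metal, per-group counts of observation states and censoring fraction.

    The censoring fraction is the share of a group's individuals whose cell
    for the metal is below the detection limit.
    """
    rows = []
    for g in sorted(set(panel.group)):
        gmask = panel.group == g
        size = int(gmask.sum())
        for j, metal in enumerate(panel.metals):
            col = panel.status[gmask, j]
            n_obs = int(np.sum(col == CellStatus.OBSERVED))
            n_bl = int(np.sum(col == CellStatus.BELOW_LIMIT))
            n_iv = int(np.sum(col == CellStatus.INTERVAL))
            rows.append({"metal": metal, "group": g, "n": size,
                         "observed": n_obs, "below_limit": n_bl, "interval": n_iv,
                         "censoring_fraction": n_bl / size})
    return pd.DataFrame(rows)
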