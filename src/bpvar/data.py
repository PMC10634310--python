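"""Panel data container, file I/O and variable-preparation transforms.

The central object is :class:`PanelDataset`, a long (tidy) country-year table
of jointly endogenous variables.  Preparation steps mirror standard practice
for macro-health panels: a quarterly uncertainty index is annualized by
averaging available quarters, all level variables except the uncertainty
index are taken in natural logs, and the panel is balanced by listwise
deletion of countries with incomplete coverage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ID_COLUMNS = ("country", "year")
GROUP_KEYS = ("market_class", "income_tier")


class PanelValidationError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass
class PanelDataset:
    """Long-format balanced-or-ragged panel of country-year observations.

    Parameters
    ----------
    frame
        DataFrame with columns ``country``, ``year`` and one numeric column
        per endogenous variable.  ``(country, year)`` pairs must be unique.
    variable_order
        Endogenous variables in their recursive (Cholesky) ordering.  The
        ordering is part of the identification scheme: the uncertainty proxy
        comes first, the health indicator last.
    group_labels
        Optional mapping ``country -> {"market_class": ..., "income_tier": ...}``
        used for subsample analysis.
    """

    frame: pd.DataFrame
    variable_order: list[str]
    group_labels: dict[str, dict[str, str]] | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.frame.columns]
        if missing:
            raise PanelValidationError(f"panel is missing id columns {missing}")
        if not self.variable_order:
            raise PanelValidationError("variable_order must be non-empty")
        absent = [v for v in self.variable_order if v not in self.frame.columns]
        if absent:
            raise PanelValidationError(f"variables {absent} not in table")
        if len(set(self.variable_order)) != len(self.variable_order):
            raise PanelValidationError("variable_order contains duplicates")
        dup = self.frame.duplicated(subset=list(ID_COLUMNS))
        if dup.any():
            pairs = self.frame.loc[dup, list(ID_COLUMNS)].head(3).to_dict("records")
            raise PanelValidationError(f"duplicate (country, year) pairs, e.g. {pairs}")
        for v in self.variable_order:
            if not np.issubdtype(self.frame[v].dtype, np.number):
                raise PanelValidationError(f"variable {v!r} is not numeric")
        self.frame = (
            self.frame[list(ID_COLUMNS) + self.variable_order]
            .sort_values(list(ID_COLUMNS), kind="mergesort")
            .reset_index(drop=True)
        )

    # -- basic accessors ---------------------------------------------------

    @property
    def countries(self) -> list[str]:
        return list(pd.unique(self.frame["country"]))

    @property
    def n_countries(self) -> int:
        return self.frame["country"].nunique()

    @property
    def n_vars(self) -> int:
        return len(self.variable_order)

    def is_balanced(self) -> bool:
        counts = self.frame.groupby("country", sort=False).size()
        if counts.nunique() != 1:
            return False
        return not self.frame[self.variable_order].isna().any().any()

    @property
    def n_years(self) -> int:
        counts = self.frame.groupby("country", sort=False).size()
        if counts.nunique() != 1:
            raise PanelValidationError("panel is unbalanced; n_years undefined")
        return int(counts.iloc[0])

    def to_arrays(self) -> np.ndarray:
        """Return the balanced panel as an (N, T, M) array in variable order."""
        if not self.is_balanced():
            raise PanelValidationError("panel must be balanced")
        n, t, m = self.n_countries, self.n_years, self.n_vars
        return self.frame[self.variable_order].to_numpy(float).reshape(n, t, m)

    def copy_with(self, frame: pd.DataFrame) -> "PanelDataset":
        return PanelDataset(frame.copy(), list(self.variable_order), self.group_labels)


@dataclass(frozen=True)
class PrepConfig:
    """Which variables are logged; the uncertainty proxy is never logged."""

    log_variables: frozenset[str]
    uncertainty_variable: str = "uncertainty"

    def __post_init__(self) -> None:
        if self.uncertainty_variable in self.log_variables:
            raise ValueError("the uncertainty variable must not be log-transformed")


# -- I/O -------------------------------------------------------------------


def read_panel(
    path: str | Path,
    variable_order: list[str] | None = None,
    groups_path: str | Path | None = None,
) -> PanelDataset:
    """Read a long-format delimited panel file (header: country,year,vars...)."""
    frame = pd.read_csv(path)
    if variable_order is None:
        variable_order = [c for c in frame.columns if c not in ID_COLUMNS]
    groups = None
    if groups_path is not None:
        groups = json.loads(Path(groups_path).read_text())
    return PanelDataset(frame, variable_order, groups)


def write_panel(panel: PanelDataset, path: str | Path, groups_path: str | Path | None = None) -> None:
    panel.frame.to_csv(path, index=False)
    if groups_path is not None and panel.group_labels is not None:
        Path(groups_path).write_text(json.dumps(panel.group_labels, indent=1, sort_keys=True))


# -- preparation transforms ------------------------------------------------


def quarterly_to_annual(quarterly: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Annualize a quarterly series by averaging the available quarters.

    Expects columns ``country``, ``year``, ``quarter``, and a value column;
    returns ``country``, ``year``, value.  Countries with ragged quarterly
    coverage are averaged over whatever quarters are present.
    """
    required = {"country", "year", "quarter", value}
    if not required.issubset(quarterly.columns):
        raise ValueError(f"quarterly table needs columns {sorted(required)}")
    if quarterly.empty:
        raise ValueError("empty quarterly series")
    bad = ~quarterly["quarter"].isin([1, 2, 3, 4])
    if bad.any():
        raise ValueError("quarter values must be in 1..4")
    out = (
        quarterly.groupby(["country", "year"], sort=True, as_index=False)[value]
        .mean()
    )
    return out


def apply_logs(panel: PanelDataset, prep: PrepConfig) -> PanelDataset:
    """Replace the configured variables by their natural logarithms.

    Raises on non-positive values, naming the offending cell: the health
    indicators here (death, mortality and suicide rates, expenditure levels)
    are strictly positive in any usable panel, so a zero signals a data
    problem rather than something to patch over.
    """
    frame = panel.frame.copy()
    for v in prep.log_variables:
        if v not in panel.variable_order:
            raise ValueError(f"log variable {v!r} not in panel")
        col = frame[v].to_numpy(float)
        bad = ~(col > 0)
        if bad.any():
            row = frame.loc[np.flatnonzero(bad)[0]]
            raise ValueError(
                f"non-positive value for {v!r} at country={row['country']!r}, "
                f"year={int(row['year'])}: {row[v]}"
            )
        frame[v] = np.log(col)
    return panel.copy_with(frame)


def balance_panel(panel: PanelDataset, year_range: tuple[int, int]) -> PanelDataset:
    """Keep countries fully observed on every year of ``year_range``.

    Countries with any missing year or missing variable value inside the
    range are dropped (listwise deletion) and logged.
    """
    start, end = year_range
    years = set(range(start, end + 1))
    frame = panel.frame[panel.frame["year"].between(start, end)]
    keep = []
    for country, sub in frame.groupby("country", sort=False):
        if set(sub["year"]) == years and not sub[panel.variable_order].isna().any().any():
            keep.append(country)
        else:
            logger.info("balance_panel: dropping %s (incomplete %d-%d coverage)", country, start, end)
    if not keep:
        raise PanelValidationError(f"no country fully observed over {start}-{end}")
    out = frame[frame["country"].isin(keep)]
    return panel.copy_with(out)


def subset_by_group(panel: PanelDataset, key: str, value: str) -> PanelDataset:
    """Restrict the panel to countries with ``group_labels[country][key] == value``."""
    if panel.group_labels is None:
        raise ValueError("panel has no group labels")
    if key not in GROUP_KEYS:
        raise ValueError(f"unknown group key {key!r}; expected one of {GROUP_KEYS}")
    known = {labels[key] for labels in panel.group_labels.values()}
    if value not in known:
        raise ValueError(f"unknown label {value!r} for {key!r}; known: {sorted(known)}")
    members = {c for c, labels in panel.group_labels.items() if labels[key] == value}
    out = panel.frame[panel.frame["country"].isin(members)]
    return panel.copy_with(out)
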