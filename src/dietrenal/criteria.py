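"""Binary criteria of the 17-item energy-reduced Mediterranean diet screener.

The screener scores one point per item when a fixed, population-independent
criterion on a dietary variable is met (e.g. "vegetables >= 2 units/day").
Criteria live in a YAML preset so that alternative phrasings of ambiguous
items can be swapped without touching code; :func:`load_criteria` reads the
presets shipped with the package or a user-supplied file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, MissingDataError

_VALID_OPS = {"ge", "gt", "le", "lt", "between"}


@dataclass(frozen=True)
class Criterion:
    """One screener item: a threshold (or interval) on a single variable."""

    item: int
    label: str
    variable: str
    op: str
    threshold: float | None = None
    bounds_by_sex: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.op not in _VALID_OPS:
            raise ConfigurationError(f"criterion {self.item}: unknown op {self.op!r}")
        if self.op == "between":
            if not self.bounds_by_sex:
                raise ConfigurationError(
                    f"criterion {self.item}: 'between' requires bounds_by_sex"
                )
        elif self.threshold is None:
            raise ConfigurationError(f"criterion {self.item}: threshold required")

    def evaluate(self, value, sex=None):
        """Vectorized truth of the criterion; `value` may be scalar or array."""
        x = np.asarray(value, dtype=float)
        if self.op == "ge":
            return x >= self.threshold
        if self.op == "gt":
            return x > self.threshold
        if self.op == "le":
            return x <= self.threshold
        if self.op == "lt":
            return x < self.threshold
        # between: inclusive, sex-specific window
        if sex is None:
            raise MissingDataError(
                f"criterion {self.item} ({self.variable}) needs sex for its window"
            )
        sex_arr = np.asarray(sex)
        lo = np.empty(sex_arr.shape, dtype=float)
        hi = np.empty(sex_arr.shape, dtype=float)
        for s, (a, b) in self.bounds_by_sex.items():
            mask = sex_arr == s
            lo[mask] = a
            hi[mask] = b
        unknown = ~np.isin(sex_arr, list(self.bounds_by_sex))
        if np.any(unknown):
            bad = np.unique(sex_arr[unknown])
            raise ConfigurationError(
                f"criterion {self.item}: no bounds for sex value(s) {bad.tolist()}"
            )
        out = (x >= lo) & (x <= hi)
        return out if out.shape else bool(out)


class CriteriaTable:
    """The ordered set of 17 screener criteria for one preset."""

    def __init__(self, criteria: list[Criterion], preset: str = "custom"):
        if len(criteria) != 17:
            raise ConfigurationError(
                f"a screener criteria table needs exactly 17 items, got {len(criteria)}"
            )
        items = [c.item for c in criteria]
        if sorted(items) != list(range(1, 18)):
            raise ConfigurationError("criteria items must be exactly 1..17")
        self.criteria = sorted(criteria, key=lambda c: c.item)
        self.preset = preset

    def __len__(self) -> int:
        return 17

    def __iter__(self):
        return iter(self.criteria)

    def __getitem__(self, item: int) -> Criterion:
        """Look up a criterion by its 1-based item number."""
        return self.criteria[item - 1]

    @property
    def variables(self) -> list[str]:
        return [c.variable for c in self.criteria]


def load_criteria(preset: str = "printed", path: str | Path | None = None) -> CriteriaTable:
    """Load a criteria preset from the packaged YAML (or a user file).

    Parameters
    ----------
    preset
        Name of the preset inside the YAML file. The package ships
        ``printed`` (default) and ``reversed_breads``.
    path
        Optional path to a YAML file with the same schema, overriding the
        packaged presets.
    """
    if path is None:
        text = resources.files("dietrenal.data").joinpath("ermed_criteria.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    presets = doc.get("presets", {})
    if preset not in presets:
        raise ConfigurationError(
            f"unknown criteria preset {preset!r}; available: {sorted(presets)}"
        )
    rows = []
    for entry in presets[preset]:
        bounds = entry.get("bounds_by_sex")
        if bounds is not None:
            bounds = {k: (float(v[0]), float(v[1])) for k, v in bounds.items()}
        rows.append(
            Criterion(
                item=int(entry["item"]),
                label=str(entry["label"]),
                variable=str(entry["variable"]),
                op=str(entry["op"]),
                threshold=entry.get("threshold"),
                bounds_by_sex=bounds,
            )
        )
    return CriteriaTable(rows, preset=preset)
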