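"""Collinearity screening of candidate bioclimatic variables.

Pairs of bioclimatic summaries are often near-duplicates (e.g. annual mean
temperature vs. mean temperature of the warmest quarter). Before fitting,
the candidate set is screened by pairwise Pearson correlation and reduced so
that no two retained variables correlate at |r| >= cutoff (default 0.75).
Which member of a correlated group survives is a biological judgement, so it
enters as an explicit, auditable priority list rather than a hidden rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridStack


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variables)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape does not match variables")

    def lookup(self, a: str, b: str) -> float:
        return float(self.r[self.variables.index(a), self.variables.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


def correlation_matrix(stack: GridStack,
                       cells: np.ndarray | None = None) -> CorrelationMatrix:
    """Pairwise Pearson r between layers over evaluation cells.

    ``cells`` is an optional (n, 2) array of (row, col) indices; by default
    all unmasked cells are used. A constant variable has no defined
    correlation and is reported as an error naming it.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least 2 variables")
    if cells is None:
        data = stack.unmasked_values()
        cols = [data[n] for n in names]
    else:
        cells = np.asarray(cells, dtype=int)
        cols = [stack[n].values[cells[:, 0], cells[:, 1]] for n in names]
    m = len(cols[0])
    if m < 3:
        raise ValueError("need at least 3 evaluation cells")
    X = np.column_stack(cols)
    sd = X.std(axis=0)
    for j, name in enumerate(names):
        if sd[j] == 0:
            raise ValueError(f"variable {name!r} is constant over the evaluation cells; "
                             "its correlation is undefined")
    r = np.corrcoef(X, rowvar=False)
    # exact diagonal and symmetry regardless of rounding
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(variables=list(names), r=r)


def select_variables(corr: CorrelationMatrix, priority: list[str] | None = None,
                     cutoff: float = 0.75) -> list[str]:
    """Greedy retention scan: keep a variable iff |r| < cutoff vs. all kept so far.

    Variables are scanned in ``priority`` order (default: matrix order);
    |r| >= cutoff excludes. The result is maximal under the rule: no skipped
    variable could be added back without violating the cutoff.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if priority is None:
        priority = list(corr.variables)
    missing = set(corr.variables) - set(priority)
    if missing:
        raise ValueError(f"priority list does not cover variables: {sorted(missing)}")
    retained: list[str] = []
    for name in priority:
        if name not in corr.variables:
            continue
        if all(abs(corr.lookup(name, kept)) < cutoff for kept in retained):
            retained.append(name)
    return retained


#: the six variables of the published final models, first in priority
DEFAULT_PRIORITY_HEAD = ["bio1", "bio2", "bio7", "bio12", "bio14", "bio15"]


def default_priority(variables: list[str]) -> list[str]:
    """Priority order: the published final six first, then the rest.

    Remaining variables follow in numeric bio-index order where parseable,
    otherwise lexicographic.
    """
    head = [v for v in DEFAULT_PRIORITY_HEAD if v in variables]
    rest = [v for v in variables if v not in head]

    def key(name: str):
        if name.startswith("bio") and name[3:].isdigit():
            return (0, int(name[3:]))
        return (1, name)

    return head + sorted(rest, key=key)
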