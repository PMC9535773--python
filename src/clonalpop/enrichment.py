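"""Habitat / geography enrichment of strain groups.

Hybridization-event groups are cross-tabulated against habitat class or
continent and tested with Fisher's exact test.  Tables larger than 2x2 use a
Monte-Carlo p-value: random tables with the observed margins are generated
by permuting category labels, and the p-value is the (add-one corrected)
fraction whose probability under the fixed-margin null does not exceed the
observed table's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import ValidationError
from .io_formats import StrainMeta


@dataclass
class ContingencyResult:
    table: pd.DataFrame  # groups x categories
    n_excluded: int  # strains without a group or a field value


def build_contingency(
    meta: Sequence[StrainMeta],
    groups: Mapping[str, str],
    field: str = "habitat_class",
) -> ContingencyResult:
    """Cross-tabulate strain groups against a metadata field.

    Strains missing from ``groups`` or with an empty field value are excluded
    and counted, never silently dropped.
    """
    rows = []
    excluded = 0
    for m in meta:
        value = getattr(m, field, "") or ""
        group = groups.get(m.strain_id)
        if group is None or not str(value).strip():
            excluded += 1
            continue
        rows.append((str(group), str(value)))
    if not rows:
        raise ValidationError("contingency table is empty after exclusions")
    df = pd.DataFrame(rows, columns=["group", field])
    table = pd.crosstab(df["group"], df[field])
    return ContingencyResult(table, excluded)


def _as_array(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2:
        raise ValidationError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValidationError("negative counts in contingency table")
    return arr


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sum of hypergeometric probabilities of all fixed-margin tables whose
    probability does not exceed the observed table's.
    """
    arr = _as_array(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got {arr.shape}")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _log_table_prob(arr: np.ndarray) -> float:
    """Log fixed-margin (multivariate hypergeometric) probability of a table."""
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    n = arr.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(arr + 1).sum()
    )


def fisher_exact_mc(
    table, n_sim: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo Fisher exact p for an r x c table.

    Null tables with the observed margins arise from random permutation of
    the column category labels over individuals.  The estimator is the
    add-one corrected ``(1 + #{P(sim) <= P(obs)}) / (n_sim + 1)``, which is
    biased upward and therefore never anti-conservative.
    """
    arr = _as_array(table)
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("degenerate margins: empty row or column")
    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(arr)
    # individuals: row label per individual, column labels to permute
    row_ids = np.repeat(np.arange(len(row)), row)
    col_ids = np.repeat(np.arange(len(col)), col)
    hits = 0
    r, c = arr.shape
    for _ in range(n_sim):
        perm = rng.permutation(col_ids)
        sim = np.zeros((r, c), dtype=np.int64)
        np.add.at(sim, (row_ids, perm), 1)
        if _log_table_prob(sim) <= obs_logp + 1e-9:
            hits += 1
    return (1 + hits) / (n_sim + 1)


def group_enrichment(
    meta: Sequence[StrainMeta],
    groups: Mapping[str, str],
    field: str = "habitat_class",
    n_sim: int = 10_000,
    seed: int = 0,
) -> tuple[float, ContingencyResult]:
    """Convenience wrapper: build the table and return its Monte-Carlo p."""
    built = build_contingency(meta, groups, field)
    return fisher_exact_mc(built.table, n_sim=n_sim, seed=seed), built
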