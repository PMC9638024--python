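"""Oligomer taxonomy, per-field census metrics and condition comparison.

Association groups are classified by their per-channel protomer counts
``(n_a, n_b)`` into the receptor-census taxonomy: monomers, homodimers,
low-order homo-oligomers (3–5), heterodimers, heterotrimers,
heterotetramers, heteropentamers, and higher-order (≥ 6) variants of
both kinds.  Low-order complexes (2–5 receptors) are the biologically
meaningful signal; complexes of ≥ 6 receptors are density-sensitive and
reported separately.

Per-field summaries mirror the standard census panels:

* heteromer burden — molecules in heteromeric groups as a percentage of
  **all** receptors in the field;
* heteromer composition — each heteromeric class as a percentage of
  **total heteromeric groups**;
* stoichiometry breakdowns within heterotrimers and heterotetramers,
  labelled ``"<n_a>EP2:<n_b>OTR"``.

Condition-level aggregation averages fields (cells) within an
experiment first, then reports mean ± SEM across experiments — n is the
number of independent experiments, not cells.  Conditions are compared
with the unpaired two-tailed Student's t test (pooled variance; Welch's
variant behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .association import AnalysisParams, AssociationGroup

__all__ = [
    "OligomerClass",
    "FieldCensus",
    "CensusSummary",
    "classify_group",
    "census_field",
    "aggregate_condition",
    "compare_conditions",
]

HETERO_SIZE_NAMES = {2: "heterodimer", 3: "heterotrimer", 4: "heterotetramer", 5: "heteropentamer"}
HOMO_SIZE_NAMES = {2: "homodimer", 3: "homotrimer", 4: "homotetramer", 5: "homopentamer"}


@dataclass(frozen=True)
class OligomerClass:
    """Taxonomic label of one association group plus its stoichiometry."""

    label: str
    n_a: int
    n_b: int

    @property
    def size(self) -> int:
        return self.n_a + self.n_b

    @property
    def is_heteromer(self) -> bool:
        return self.n_a >= 1 and self.n_b >= 1

    @property
    def stoichiometry(self) -> Optional[str]:
        """``"<n_a>EP2:<n_b>OTR"`` for heteromeric classes, else None."""
        if not self.is_heteromer:
            return None
        return f"{self.n_a}EP2:{self.n_b}OTR"


def classify_group(group: AssociationGroup, params: AnalysisParams | None = None) -> OligomerClass:
    """Classify a group by its per-channel counts.

    Size 1 → monomer; both channels present → hetero- class named by
    size; single channel → homo- class by size; size ≥
    ``higher_order_min`` (default 6) → the higher-order variant.
    """
    params = params or AnalysisParams()
    n_a, n_b = group.n_a, group.n_b
    size = n_a + n_b
    if size == 0:
        raise ValueError("cannot classify an empty group")
    hetero = n_a >= 1 and n_b >= 1
    if size == 1:
        label = "monomer"
    elif size >= params.higher_order_min:
        label = "hetero-higher" if hetero else "homomer-higher"
    elif hetero:
        label = HETERO_SIZE_NAMES[size]
    else:
        label = HOMO_SIZE_NAMES[size]
    return OligomerClass(label=label, n_a=n_a, n_b=n_b)


@dataclass
class FieldCensus:
    """Per-field census metrics.

    Percentages with an empty denominator are ``None`` (absent), never 0:
    a field without heteromers has no heteromer composition, not a
    composition of zeros.
    """

    n_molecules: int
    n_groups: int
    pct_molecules_in_heteromers: Optional[float]
    pct_molecules_monomeric: Optional[float]
    pct_molecules_in_homomers: Optional[float]
    heteromer_composition: Optional[Dict[str, float]]
    trimer_stoich: Optional[Dict[str, float]]
    tetramer_stoich: Optional[Dict[str, float]]
    class_counts: Dict[str, int]

    def to_metrics(self) -> Dict[str, float]:
        """Flatten to ``metric name → value`` (absent metrics omitted)."""
        out: Dict[str, float] = {
            "n_molecules": float(self.n_molecules),
            "n_groups": float(self.n_groups),
        }
        for key in (
            "pct_molecules_in_heteromers",
            "pct_molecules_monomeric",
            "pct_molecules_in_homomers",
        ):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        for prefix, table in (
            ("heteromer_composition", self.heteromer_composition),
            ("trimer_stoich", self.trimer_stoich),
            ("tetramer_stoich", self.tetramer_stoich),
        ):
            if table is not None:
                for k, v in table.items():
                    out[f"{prefix}/{k}"] = v
        return out


def census_field(
    groups: Sequence[AssociationGroup], params: AnalysisParams | None = None
) -> FieldCensus:
    """Compute the Figure-5-style per-field metrics from a group partition."""
    params = params or AnalysisParams()
    classes = [classify_group(g, params) for g in groups]
    n_molecules = sum(c.size for c in classes)
    if n_molecules == 0:
        return FieldCensus(
            n_molecules=0,
            n_groups=0,
            pct_molecules_in_heteromers=None,
            pct_molecules_monomeric=None,
            pct_molecules_in_homomers=None,
            heteromer_composition=None,
            trimer_stoich=None,
            tetramer_stoich=None,
            class_counts={},
        )

    hetero = [c for c in classes if c.is_heteromer]
    mono = [c for c in classes if c.size == 1]
    homo = [c for c in classes if c.size >= 2 and not c.is_heteromer]

    def pct(num: float, den: float) -> float:
        return 100.0 * num / den

    comp: Optional[Dict[str, float]] = None
    if hetero:
        comp = {}
        for c in hetero:
            comp[c.label] = comp.get(c.label, 0.0) + 1.0
        comp = {k: pct(v, len(hetero)) for k, v in sorted(comp.items())}

    def stoich_table(size: int) -> Optional[Dict[str, float]]:
        members = [c for c in hetero if c.size == size]
        if not members:
            return None
        table: Dict[str, float] = {}
        for c in members:
            table[c.stoichiometry] = table.get(c.stoichiometry, 0.0) + 1.0
        return {k: pct(v, len(members)) for k, v in sorted(table.items())}

    counts: Dict[str, int] = {}
    for c in classes:
        counts[c.label] = counts.get(c.label, 0) + 1

    return FieldCensus(
        n_molecules=n_molecules,
        n_groups=len(classes),
        pct_molecules_in_heteromers=pct(sum(c.size for c in hetero), n_molecules),
        pct_molecules_monomeric=pct(len(mono), n_molecules),
        pct_molecules_in_homomers=pct(sum(c.size for c in homo), n_molecules),
        heteromer_composition=comp,
        trimer_stoich=stoich_table(3),
        tetramer_stoich=stoich_table(4),
        class_counts=counts,
    )


@dataclass
class CensusSummary:
    """Per-field metric rows plus condition-level mean ± SEM.

    ``per_field``: columns field_id, experiment, condition, metric, value.
    ``per_condition``: columns condition, metric, mean, sem, n_experiments
    (sem is NaN when a condition has a single experiment).
    """

    per_field: pd.DataFrame
    per_condition: pd.DataFrame

    def condition_values(self, condition: str, metric: str) -> np.ndarray:
        """Per-experiment means for one metric (inputs to a t test)."""
        sub = self.per_field[
            (self.per_field["condition"] == condition)
            & (self.per_field["metric"] == metric)
        ]
        return sub.groupby("experiment")["value"].mean().to_numpy()


def aggregate_condition(
    field_metrics: Iterable[Tuple[str, str, str, Dict[str, float]]],
) -> CensusSummary:
    """Aggregate per-field metrics into a :class:`CensusSummary`.

    Parameters
    ----------
    field_metrics : iterable of ``(field_id, experiment, condition,
        metrics)`` where ``metrics`` maps metric name → value (as from
        :meth:`FieldCensus.to_metrics`).

    Cells (fields) are first averaged within each experiment; the mean
    and SEM are then taken across experiments, so n equals the number of
    independent experiments.
    """
    rows = []
    for field_id, experiment, condition, metrics in field_metrics:
        for metric, value in metrics.items():
            rows.append(
                {
                    "field_id": field_id,
                    "experiment": experiment,
                    "condition": condition,
                    "metric": metric,
                    "value": float(value),
                }
            )
    per_field = pd.DataFrame(
        rows, columns=["field_id", "experiment", "condition", "metric", "value"]
    )
    cond_rows = []
    if len(per_field):
        per_exp = (
            per_field.groupby(["condition", "metric", "experiment"])["value"]
            .mean()
            .reset_index()
        )
        for (condition, metric), sub in per_exp.groupby(["condition", "metric"]):
            vals = sub["value"].to_numpy()
            n = len(vals)
            sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else np.nan
            cond_rows.append(
                {
                    "condition": condition,
                    "metric": metric,
                    "mean": float(np.mean(vals)),
                    "sem": sem,
                    "n_experiments": n,
                }
            )
    per_condition = pd.DataFrame(
        cond_rows, columns=["condition", "metric", "mean", "sem", "n_experiments"]
    )
    return CensusSummary(per_field=per_field, per_condition=per_condition)


def compare_conditions(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> Tuple[float, float]:
    """Unpaired two-tailed Student's t test on per-experiment values.

    Returns ``(t, p)`` with the classical pooled-variance statistic and
    df = n₁ + n₂ − 2 (``welch=True`` switches to Welch's unequal-variance
    test).  Raises ``ValueError`` for n < 2 or zero pooled variance,
    where the statistic is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_ss = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    if pooled_ss == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
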