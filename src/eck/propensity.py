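"""Catalytic-residue propensities and functional role profiles.

The catalytic propensity of residue type *r* in an enzyme class *C* is

    P(r, C) = (catalytic residues of type r in C / all catalytic residues in C)
              -------------------------------------------------------------
              (residues of type r in C / all residues in C)

i.e. the share of the catalytic toolkit contributed by *r*, normalized by its
background abundance.  A value above 1 means the residue is more catalytic
than chance; below 1, less.  The composition-weighted mean of a propensity
column is exactly 1, which the table asserts.

The same tallies reorganized by functional role give role profiles: how often
each catalytic entity kind (residue, metal ion, organic cofactor) performs
activation, steric control, stabilization, proton / hydrogen-radical /
electron / hydride shuttling or covalent catalysis, per EC class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import ALL_ROLES, AMINO_ACIDS, Dataset, ENTITY_KINDS

__all__ = [
    "PropensityTable",
    "RoleProfile",
    "background_composition",
    "catalytic_composition",
    "catalytic_propensity",
    "role_profile",
    "acting_part_summary",
    "PropensityAnalyzer",
]

ALL_CLASSES_LABEL = "all"


def _class_labels(dataset: Dataset) -> List[object]:
    return list(dataset.ec_classes) + [ALL_CLASSES_LABEL]


def _selection(dataset: Dataset, ec_class):
    if ec_class in (None, ALL_CLASSES_LABEL):
        return dataset.records
    return dataset.records_of_class(ec_class)


def background_composition(dataset: Dataset, ec_class=None) -> pd.Series:
    """Residue-type frequencies over all chain residues of the selection.

    ``ec_class`` is an EC class digit or ``None``/``"all"``; ``X`` residues
    are excluded from numerator and denominator.  Frequencies sum to 1.
    """
    records = _selection(dataset, ec_class)
    if not records:
        raise ValueError(f"no records in selection (class {ec_class!r})")
    counts = pd.Series(0, index=list(AMINO_ACIDS), dtype=float)
    for record in records:
        for chain in record.chains:
            for letter, n in zip(*np.unique(list(chain.sequence), return_counts=True)):
                if letter in counts.index:
                    counts[letter] += int(n)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"selection for class {ec_class!r} has no standard residues")
    return counts / total


def catalytic_composition(dataset: Dataset, ec_class=None) -> pd.Series:
    """Residue-type frequencies over catalytic annotations of the selection.

    Each annotation counts once per record (records are non-redundant at the
    mechanism level, so no family-size down-weighting is applied).
    """
    records = _selection(dataset, ec_class)
    counts = pd.Series(0, index=list(AMINO_ACIDS), dtype=float)
    for record in records:
        for ann in record.catalytic_annotations:
            counts[ann.residue_type] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no catalytic annotations in selection (class {ec_class!r})")
    return counts / total


@dataclass
class PropensityTable:
    """Residue-type x EC-class propensity matrix with its underlying tallies.

    ``values`` has one column per EC class present plus ``"all"``; cells with
    zero background count are NaN and listed in ``undefined`` rather than
    silently zeroed.  ``counts`` holds the four tallies behind every cell:
    catalytic-of-type, catalytic-total, background-of-type, background-total.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    undefined: Set[Tuple[str, object]] = field(default_factory=set)

    def check_weighted_mean(self, tol: float = 1e-9) -> None:
        """Assert the composition-weighted mean of each fully defined column is 1."""
        for column in self.values.columns:
            if any(col == column for _, col in self.undefined):
                continue
            bg = self.counts.xs(column, level="ec_class")["background_count"]
            weights = bg / bg.sum()
            mean = float((weights * self.values[column]).sum())
            if abs(mean - 1.0) > tol:
                raise AssertionError(
                    f"weighted mean of class {column!r} propensities is {mean}, not 1"
                )


def catalytic_propensity(
    dataset: Dataset, convention: str = "fraction_of_catalytic"
) -> PropensityTable:
    """Compute the propensity table over every EC class present plus "all".

    ``convention`` names the reading of the ratio: ``"fraction_of_catalytic"``
    divides the share of catalytic residues that are of type *r* by the
    background share of *r*; ``"per_residue_rate"`` divides the fraction of
    type-*r* residues that are catalytic by the overall catalytic fraction.
    The two are algebraically identical — both are exposed so the intended
    reading can be stated explicitly at the call site.
    """
    if convention not in ("fraction_of_catalytic", "per_residue_rate"):
        raise ValueError(f"unknown convention {convention!r}")
    labels = _class_labels(dataset)
    values = {}
    count_rows = []
    undefined: Set[Tuple[str, object]] = set()
    for label in labels:
        records = _selection(dataset, label)
        bg_counts = pd.Series(0.0, index=list(AMINO_ACIDS))
        cat_counts = pd.Series(0.0, index=list(AMINO_ACIDS))
        for record in records:
            for chain in record.chains:
                for letter in chain.sequence:
                    if letter in bg_counts.index:
                        bg_counts[letter] += 1
            for ann in record.catalytic_annotations:
                cat_counts[ann.residue_type] += 1
        cat_total, bg_total = cat_counts.sum(), bg_counts.sum()
        if cat_total == 0:
            # a class with sequences but no catalytic annotations is flagged
            # wholesale instead of fabricating a column of zeros
            column = pd.Series(np.nan, index=list(AMINO_ACIDS))
            undefined.update((aa, label) for aa in AMINO_ACIDS)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                column = (cat_counts / cat_total) / (bg_counts / bg_total)
            for aa in AMINO_ACIDS:
                if bg_counts[aa] == 0:
                    column[aa] = np.nan
                    undefined.add((aa, label))
        values[label] = column
        count_rows.extend(
            {
                "residue": aa,
                "ec_class": label,
                "catalytic_count": int(cat_counts[aa]),
                "catalytic_total": int(cat_total),
                "background_count": int(bg_counts[aa]),
                "background_total": int(bg_total),
            }
            for aa in AMINO_ACIDS
        )
    table = PropensityTable(
        values=pd.DataFrame(values, index=list(AMINO_ACIDS)),
        counts=pd.DataFrame(count_rows).set_index(["residue", "ec_class"]),
        undefined=undefined,
    )
    table.check_weighted_mean()
    return table


def role_profile(dataset: Dataset) -> pd.DataFrame:
    """Tally (entity kind, role) incidences per EC class.

    An annotation with *k* roles contributes *k* incidences; a record with
    nodes in several classes contributes to each of its classes and to
    ``"all"`` once.  Rows are a (entity_kind, role) MultiIndex over the three
    entity kinds and all eight role categories.
    """
    labels = _class_labels(dataset)
    index = pd.MultiIndex.from_product(
        [list(ENTITY_KINDS), list(ALL_ROLES)], names=["entity_kind", "role"]
    )
    profile = pd.DataFrame(0, index=index, columns=labels, dtype=int)
    for record in dataset:
        classes = sorted({n.class_digit for n in record.ec_nodes})
        columns = classes + [ALL_CLASSES_LABEL]
        for ann in record.catalytic_annotations:
            for role in ann.roles:
                for col in columns:
                    profile.loc[("residue", role), col] += 1
        for cof in record.cofactors:
            for role in cof.roles:
                for col in columns:
                    profile.loc[(cof.entity_kind, role), col] += 1
    return profile


@dataclass(frozen=True)
class RoleProfile:
    """Entity-kind x role x EC-class incidence counts."""

    counts: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts[ALL_CLASSES_LABEL].sum())


def acting_part_summary(dataset: Dataset) -> pd.DataFrame:
    """Per-residue-type fractions of side-chain vs main-chain catalytic use.

    Rows are the residue types with at least one catalytic annotation;
    columns ``side_chain``, ``main_chain_NH``, ``main_chain_CO`` sum to 1
    per row.
    """
    counts: Dict[str, pd.Series] = {}
    for record in dataset:
        for ann in record.catalytic_annotations:
            row = counts.setdefault(
                ann.residue_type,
                pd.Series(0.0, index=["side_chain", "main_chain_NH", "main_chain_CO"]),
            )
            row[ann.acting_part] += 1
    if not counts:
        raise ValueError("no catalytic annotations in dataset")
    table = pd.DataFrame(counts).T.sort_index()
    return table.div(table.sum(axis=1), axis=0)


class PropensityAnalyzer(BaseEstimator):
    """Compute propensity table, role profiles and acting-part summary.

    Attributes (after :meth:`fit`)
    ------------------------------
    table_ : PropensityTable
    role_profile_ : RoleProfile
    acting_parts_ : pandas.DataFrame
    background_ : pandas.Series  (whole-dataset composition)
    """

    def __init__(self, convention: str = "fraction_of_catalytic") -> None:
        self.convention = convention

    def fit(self, X: Dataset, y=None) -> "PropensityAnalyzer":
        if not isinstance(X, Dataset):
            raise TypeError("X must be an eck Dataset")
        self.table_ = catalytic_propensity(X, self.convention)
        self.role_profile_ = RoleProfile(role_profile(X))
        self.acting_parts_ = acting_part_summary(X)
        self.background_ = background_composition(X)
        return self

    def transform(self, X: Dataset) -> pd.DataFrame:
        """Return the fitted propensity matrix (residue x class)."""
        if not hasattr(self, "table_"):
            raise AttributeError("PropensityAnalyzer is not fitted")
        return self.table_.values
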