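"""Domain roles, catalytic units, architecture signatures and promiscuity.

A CATH domain is *catalytic* when it furnishes at least one catalytic
residue and *binding* when it furnishes none but at least three
substrate/intermediate/cofactor-binding residues; everything else is
*other*.  The catalytic unit is the smallest assembly conceptually required
for activity — the annotated unit when present, otherwise the chains
carrying a catalytic or binding domain — and its domain composition
(catalytic plus binding domains) is summarized as a canonical letter
signature ("A*", "A*B", "A*A*", ...) where identical CATH codes share a
letter and ``*`` marks catalytic domains.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from sklearn.base import BaseEstimator

from .records import Dataset, DomainAssignment, EnzymeRecord, ResidueAnnotation

__all__ = [
    "DomainRoleLabel",
    "CatalyticUnit",
    "ArchitectureSignature",
    "classify_domain_roles",
    "unassigned_catalytic_residues",
    "catalytic_unit",
    "architecture_signature",
    "configuration_census",
    "single_domain_fraction",
    "domain_ec_promiscuity",
    "ArchitectureAnalyzer",
]

logger = logging.getLogger(__name__)

#: Minimum binding residues for a non-catalytic domain to count as binding.
BINDING_RESIDUE_THRESHOLD = 3


@dataclass(frozen=True)
class DomainRoleLabel:
    """One domain's functional label with its residue tallies."""

    record_id: str
    chain_id: str
    cath_code: str
    label: str  # "catalytic" | "binding" | "other"
    n_catalytic_residues: int
    n_binding_residues: int


@dataclass(frozen=True)
class CatalyticUnit:
    """Chains and constituent (catalytic + binding) domains of one active site."""

    chains: Tuple[str, ...]
    domains: Tuple[DomainRoleLabel, ...]
    derived: bool  # True when no annotated unit was present


@dataclass(frozen=True)
class ArchitectureSignature:
    """Canonical domain-configuration signature of one record."""

    pattern: str
    n_bio_domains: int


def classify_domain_roles(record: EnzymeRecord) -> List[DomainRoleLabel]:
    """Label every domain of the record as catalytic, binding or other.

    Catalytic residues falling outside every domain segment (linker
    residues) do not contribute to any domain; retrieve them with
    :func:`unassigned_catalytic_residues`.
    """
    labels = []
    for dom in record.domains:
        n_cat = sum(
            1
            for a in record.catalytic_annotations
            if a.chain_id == dom.chain_id and dom.contains(a.position)
        )
        n_bind = sum(
            1
            for a in record.binding_annotations
            if a.chain_id == dom.chain_id and dom.contains(a.position)
        )
        if n_cat >= 1:
            label = "catalytic"
        elif n_bind >= BINDING_RESIDUE_THRESHOLD:
            label = "binding"
        else:
            label = "other"
        labels.append(
            DomainRoleLabel(record.record_id, dom.chain_id, dom.cath_code, label, n_cat, n_bind)
        )
    return labels


def unassigned_catalytic_residues(record: EnzymeRecord) -> List[ResidueAnnotation]:
    """Catalytic annotations not covered by any domain segment (QC report)."""
    out = []
    for ann in record.catalytic_annotations:
        if not any(
            dom.chain_id == ann.chain_id and dom.contains(ann.position)
            for dom in record.domains
        ):
            out.append(ann)
    if out:
        logger.info(
            "%s: %d catalytic residue(s) outside every domain segment",
            record.record_id,
            len(out),
        )
    return out


def catalytic_unit(
    record: EnzymeRecord, roles: Optional[Sequence[DomainRoleLabel]] = None
) -> CatalyticUnit:
    """Resolve the record's catalytic unit.

    The annotated ``catalytic_unit_chains`` takes precedence; otherwise the
    unit is derived as all chains carrying at least one catalytic or binding
    domain.  Raises ``ValueError`` when neither an annotation nor any
    catalytic domain exists.
    """
    if roles is None:
        roles = classify_domain_roles(record)
    functional = [r for r in roles if r.label in ("catalytic", "binding")]
    if record.catalytic_unit_chains:
        chains = tuple(dict.fromkeys(record.catalytic_unit_chains))
        derived = False
    else:
        chains = tuple(sorted({r.chain_id for r in functional}))
        derived = True
        if not chains:
            raise ValueError(
                f"{record.record_id}: no annotated catalytic unit and no "
                "catalytic or binding domain to derive one from"
            )
    unit_domains = tuple(r for r in functional if r.chain_id in chains)
    return CatalyticUnit(chains=chains, domains=unit_domains, derived=derived)


def _cath_key(code: str) -> Tuple[int, ...]:
    return tuple(int(p) for p in code.split("."))


def architecture_signature(record: EnzymeRecord) -> ArchitectureSignature:
    """Canonical catalytic-unit pattern plus biological-unit domain count.

    Unit domains are sorted catalytic-first, then by numeric CATH code;
    letters are assigned in first-occurrence order over that sorted list,
    identical CATH codes sharing a letter.  The biological-unit domain count
    honours chain multiplicity (a homodimer's chain counts its domains
    twice).
    """
    roles = classify_domain_roles(record)
    unit = catalytic_unit(record, roles)
    ordered = sorted(
        unit.domains, key=lambda r: (r.label != "catalytic", _cath_key(r.cath_code))
    )
    letters: Dict[str, str] = {}
    parts = []
    for role in ordered:
        if role.cath_code not in letters:
            if len(letters) >= len(string.ascii_uppercase):
                raise ValueError(f"{record.record_id}: more than 26 distinct unit domains")
            letters[role.cath_code] = string.ascii_uppercase[len(letters)]
        parts.append(letters[role.cath_code] + ("*" if role.label == "catalytic" else ""))
    domains_per_chain = {c.chain_id: 0 for c in record.chains}
    for dom in record.domains:
        domains_per_chain[dom.chain_id] += 1
    n_bio = sum(domains_per_chain[cid] for cid in record.biological_unit_chains)
    return ArchitectureSignature(pattern="".join(parts), n_bio_domains=n_bio)


def configuration_census(dataset: Dataset) -> pd.DataFrame:
    """Tally records by (catalytic-unit pattern, biological-unit domain count).

    Returns a DataFrame with columns ``pattern``, ``n_bio_domains`` and
    ``count``, sorted canonically; counts sum to the dataset size.
    """
    tallies: Dict[Tuple[str, int], int] = {}
    for record in dataset:
        sig = architecture_signature(record)
        key = (sig.pattern, sig.n_bio_domains)
        tallies[key] = tallies.get(key, 0) + 1
    rows = [
        {"pattern": pattern, "n_bio_domains": n_bio, "count": count}
        for (pattern, n_bio), count in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["pattern", "n_bio_domains", "count"])


def single_domain_fraction(dataset: Dataset) -> float:
    """Fraction of records that are truly single-domain: one domain in both
    the catalytic and the biological assembly."""
    if not len(dataset):
        raise ValueError("empty dataset")
    hits = 0
    for record in dataset:
        sig = architecture_signature(record)
        unit = catalytic_unit(record)
        if sig.n_bio_domains == 1 and len(unit.domains) == 1:
            hits += 1
    return hits / len(dataset)


def domain_ec_promiscuity(
    dataset: Dataset, catalytic_only: bool = True
) -> pd.DataFrame:
    """Distinct complete EC nodes (and classes) per CATH code.

    By default only codes that are catalytic in at least one record are
    reported; their node tally covers every record carrying the code in any
    role.  Returns columns ``cath_code``, ``ec_node_count``,
    ``ec_class_count`` and ``nodes`` (semicolon-joined).
    """
    catalytic_codes = set()
    nodes_of_code: Dict[str, set] = {}
    for record in dataset:
        complete = record.complete_ec_nodes
        if not complete:
            continue
        for role in classify_domain_roles(record):
            if role.label == "catalytic":
                catalytic_codes.add(role.cath_code)
            nodes_of_code.setdefault(role.cath_code, set()).update(complete)
    codes = sorted(
        catalytic_codes if catalytic_only else nodes_of_code, key=_cath_key
    )
    rows = []
    for code in codes:
        nodes = sorted(nodes_of_code.get(code, set()))
        classes = {n.class_digit for n in nodes}
        rows.append(
            {
                "cath_code": code,
                "ec_node_count": len(nodes),
                "ec_class_count": len(classes),
                "nodes": ";".join(str(n) for n in nodes),
            }
        )
    return pd.DataFrame(
        rows, columns=["cath_code", "ec_node_count", "ec_class_count", "nodes"]
    )


def promiscuity_histograms(
    promiscuity: pd.DataFrame,
) -> Tuple[pd.Series, pd.Series]:
    """Histogram tables: number of CATH codes per EC-node count / class count."""
    by_nodes = promiscuity["ec_node_count"].value_counts().sort_index()
    by_classes = promiscuity["ec_class_count"].value_counts().sort_index()
    by_nodes.index.name = "ec_node_count"
    by_classes.index.name = "ec_class_count"
    return by_nodes, by_classes


class ArchitectureAnalyzer(BaseEstimator):
    """Classify domains, extract catalytic units and census configurations.

    Attributes (after :meth:`fit`)
    ------------------------------
    domain_roles_ : pandas.DataFrame
        One row per domain with its label and residue tallies.
    signatures_ : dict
        ``record_id -> ArchitectureSignature``.
    census_ : pandas.DataFrame
        Configuration census (pattern x biological-unit domain count).
    single_domain_fraction_ : float
    promiscuity_ : pandas.DataFrame
    unassigned_ : dict
        ``record_id -> [ResidueAnnotation, ...]`` catalytic residues outside
        every domain (QC; empty lists omitted).
    """

    def __init__(self, catalytic_only_promiscuity: bool = True) -> None:
        self.catalytic_only_promiscuity = catalytic_only_promiscuity

    def fit(self, X: Dataset, y=None) -> "ArchitectureAnalyzer":
        if not isinstance(X, Dataset):
            raise TypeError("X must be an eck Dataset")
        role_rows = []
        signatures = {}
        unassigned = {}
        for record in X:
            roles = classify_domain_roles(record)
            role_rows.extend(
                {
                    "record_id": r.record_id,
                    "chain_id": r.chain_id,
                    "cath_code": r.cath_code,
                    "label": r.label,
                    "n_catalytic_residues": r.n_catalytic_residues,
                    "n_binding_residues": r.n_binding_residues,
                }
                for r in roles
            )
            signatures[record.record_id] = architecture_signature(record)
            stray = unassigned_catalytic_residues(record)
            if stray:
                unassigned[record.record_id] = stray
        self.domain_roles_ = pd.DataFrame(
            role_rows,
            columns=[
                "record_id",
                "chain_id",
                "cath_code",
                "label",
                "n_catalytic_residues",
                "n_binding_residues",
            ],
        )
        self.signatures_ = signatures
        self.census_ = configuration_census(X)
        self.single_domain_fraction_ = (
            single_domain_fraction(X) if len(X) else float("nan")
        )
        self.promiscuity_ = domain_ec_promiscuity(X, self.catalytic_only_promiscuity)
        self.unassigned_ = unassigned
        return self
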