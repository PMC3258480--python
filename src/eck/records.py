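"""Data model for MACiE-like enzyme records.

One :class:`EnzymeRecord` describes a single mechanistically characterised
enzyme: its EC number(s), chain sequences, CATH domain assignments,
catalytic/binding residue annotations, cofactors and the composition of its
biological and catalytic units.  Residue positions are 1-based and segment
ranges are inclusive throughout (PDB-like convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "AMINO_ACIDS",
    "SEQUENCE_ALPHABET",
    "ROLE_CATEGORIES",
    "HYDRIDE_SHUTTLE",
    "ALL_ROLES",
    "ENTITY_KINDS",
    "ACTING_PARTS",
    "ESSENTIAL_RESIDUES",
    "NONPOLAR_RESIDUES",
    "ValidationError",
    "FormatError",
    "LinkageError",
    "ECNode",
    "ChainSequence",
    "DomainAssignment",
    "ResidueAnnotation",
    "CofactorAnnotation",
    "EnzymeRecord",
    "Dataset",
    "select_complete_ec",
]

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Letters allowed in a chain sequence (the 20 amino acids plus the unknown X).
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

#: Rare genetically encoded residues rejected at parse time: no mechanism
#: database entry uses them catalytically, so they are treated as input errors.
_REJECTED_RESIDUES = {"U": "selenocysteine", "O": "pyrrolysine"}

#: The seven functional role categories of catalytic entities:
#: activation, steric, stabilization, proton/H-radical/electron shuttling and
#: covalent catalysis.
ROLE_CATEGORIES: Tuple[str, ...] = (
    "activation",
    "steric",
    "stabilization",
    "proton_shuttle",
    "h_radical_shuttle",
    "electron_shuttle",
    "covalent_catalysis",
)

#: Hydride shuttling: a role available to cofactors (in practice only organic
#: ones) but not to amino-acid residues.
HYDRIDE_SHUTTLE = "hydride_shuttle"

ALL_ROLES: Tuple[str, ...] = ROLE_CATEGORIES + (HYDRIDE_SHUTTLE,)

ENTITY_KINDS: Tuple[str, ...] = ("residue", "metal_ion", "organic_cofactor")

ACTING_PARTS: Tuple[str, ...] = ("side_chain", "main_chain_NH", "main_chain_CO")

#: The ten residue types that perform almost all catalytic functions and act
#: through their side chains.
ESSENTIAL_RESIDUES = frozenset("RDCEHKSTWY")

#: Nonpolar residues, which act mainly through main-chain N-H or C=O groups.
NONPOLAR_RESIDUES = frozenset("ILPGAFMVW")

#: Roles whose performance chemically modifies the residue during the
#: reaction; annotations carrying any of these are "reactant" residues,
#: all others are "spectator" residues.
REACTANT_ROLES = frozenset(
    {"proton_shuttle", "h_radical_shuttle", "electron_shuttle", "covalent_catalysis"}
)


class ValidationError(ValueError):
    """A record or dataset violates a structural invariant."""


class FormatError(ValidationError):
    """An on-disk file is malformed (missing column, bad token)."""


class LinkageError(ValidationError):
    """An annotation refers to a chain/position that does not resolve."""


@dataclass(frozen=True, order=True)
class ECNode:
    """A four-level Enzyme Commission code; ``None`` marks an unassigned level.

    The first digit (class) broadly defines the chemistry (1 oxidoreductases,
    2 transferases, 3 hydrolases, 4 lyases, 5 isomerases, 6 ligases); the
    serial number generally defines substrate specificity.  A node is
    *complete* when all four levels are assigned.
    """

    class_digit: int
    subclass: Optional[int] = None
    sub_subclass: Optional[int] = None
    serial: Optional[int] = None

    def __post_init__(self) -> None:
        if self.class_digit not in range(1, 7):
            raise ValidationError(f"EC class digit must be 1-6, got {self.class_digit!r}")
        for name in ("subclass", "sub_subclass", "serial"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, int) or v < 1):
                raise ValidationError(f"EC {name} must be a positive integer or None, got {v!r}")

    @property
    def is_complete(self) -> bool:
        return None not in (self.subclass, self.sub_subclass, self.serial)

    @classmethod
    def from_string(cls, text: str) -> "ECNode":
        parts = text.strip().split(".")
        if len(parts) != 4:
            raise FormatError(f"EC number must have four dotted levels: {text!r}")
        values = []
        for part in parts:
            if part in ("-", ""):
                values.append(None)
            else:
                try:
                    values.append(int(part))
                except ValueError:
                    raise FormatError(f"bad EC level {part!r} in {text!r}") from None
        if values[0] is None:
            raise FormatError(f"EC class digit may not be unassigned: {text!r}")
        return cls(*values)

    def __str__(self) -> str:
        return ".".join(
            "-" if v is None else str(v)
            for v in (self.class_digit, self.subclass, self.sub_subclass, self.serial)
        )


@dataclass(frozen=True)
class ChainSequence:
    """One polypeptide chain: a short label and its amino-acid sequence."""

    chain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ValidationError("chain_id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"chain {self.chain_id!r}: sequence must be non-empty")
        for letter in set(self.sequence):
            if letter in _REJECTED_RESIDUES:
                raise ValidationError(
                    f"chain {self.chain_id!r}: {_REJECTED_RESIDUES[letter]} "
                    f"({letter!r}) is not supported"
                )
            if letter not in SEQUENCE_ALPHABET:
                raise ValidationError(
                    f"chain {self.chain_id!r}: letter {letter!r} outside the "
                    "20-amino-acid alphabet plus X"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_cath(code: str) -> Tuple[int, int, int, int]:
    parts = code.split(".")
    if len(parts) != 4:
        raise ValidationError(f"CATH code must have four dotted fields: {code!r}")
    try:
        c, a, t, h = (int(p) for p in parts)
    except ValueError:
        raise ValidationError(f"CATH code fields must be integers: {code!r}") from None
    return (c, a, t, h)


@dataclass(frozen=True)
class DomainAssignment:
    """A CATH H-level domain on one chain, as a set of residue-index segments.

    Segments are 1-based inclusive ranges, non-overlapping within one
    assignment.
    """

    chain_id: str
    cath_code: str
    segments: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        _parse_cath(self.cath_code)
        if not self.segments:
            raise ValidationError(f"domain {self.cath_code}: at least one segment required")
        last_end = 0
        for start, end in sorted(self.segments):
            if start < 1 or end < start:
                raise ValidationError(
                    f"domain {self.cath_code}: bad segment {start}-{end} "
                    "(1-based, start <= end)"
                )
            if start <= last_end:
                raise ValidationError(f"domain {self.cath_code}: overlapping segments")
            last_end = end
        object.__setattr__(self, "segments", tuple(sorted(self.segments)))

    @property
    def cath_key(self) -> Tuple[int, int, int, int]:
        """Numeric (C, A, T, H) tuple, the canonical sort key for CATH codes."""
        return _parse_cath(self.cath_code)

    def contains(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.segments)

    def __len__(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)


@dataclass(frozen=True)
class ResidueAnnotation:
    """One catalytic or substrate/cofactor-binding residue.

    Catalytic residues carry at least one functional role and are either
    "reactant" (chemically modified during the reaction) or "spectator"
    (essential but chemically unchanged).  Binding residues carry neither
    roles nor involvement.
    """

    chain_id: str
    position: int
    residue_type: str
    function_context: str  # "catalytic" | "binding"
    involvement: Optional[str] = None  # "reactant" | "spectator" (catalytic only)
    roles: frozenset = frozenset()
    acting_part: str = "side_chain"

    def __post_init__(self) -> None:
        if self.residue_type not in AMINO_ACIDS:
            raise ValidationError(f"unknown residue type {self.residue_type!r}")
        if self.position < 1:
            raise ValidationError("residue positions are 1-based")
        if self.function_context not in ("catalytic", "binding"):
            raise ValidationError(f"bad function_context {self.function_context!r}")
        if self.acting_part not in ACTING_PARTS:
            raise ValidationError(f"bad acting_part {self.acting_part!r}")
        object.__setattr__(self, "roles", frozenset(self.roles))
        bad = self.roles - set(ROLE_CATEGORIES)
        if bad:
            raise FormatError(
                f"unknown residue role(s) {sorted(bad)}; residues may carry "
                f"only {list(ROLE_CATEGORIES)}"
            )
        if self.function_context == "catalytic":
            if not self.roles:
                raise ValidationError("catalytic annotations need at least one role")
            if self.involvement not in ("reactant", "spectator"):
                raise ValidationError(
                    f"catalytic annotations need involvement reactant|spectator, "
                    f"got {self.involvement!r}"
                )
        else:
            if self.roles:
                raise ValidationError("binding annotations carry no roles")
            if self.involvement is not None:
                raise ValidationError("binding annotations carry no involvement")


@dataclass(frozen=True)
class CofactorAnnotation:
    """A catalytic cofactor: a metal ion or small organic molecule."""

    cofactor_id: str
    entity_kind: str  # "metal_ion" | "organic_cofactor"
    roles: frozenset

    def __post_init__(self) -> None:
        if self.entity_kind not in ("metal_ion", "organic_cofactor"):
            raise ValidationError(f"bad entity_kind {self.entity_kind!r}")
        object.__setattr__(self, "roles", frozenset(self.roles))
        if not self.roles:
            raise ValidationError("cofactor annotations need at least one role")
        bad = self.roles - set(ALL_ROLES)
        if bad:
            raise FormatError(f"unknown cofactor role(s) {sorted(bad)}")


@dataclass(frozen=True)
class EnzymeRecord:
    """One enzyme entry with all of its annotations.

    ``biological_unit_chains`` is a multiset (chain ids may repeat, e.g. a
    homodimer lists its chain twice); ``catalytic_unit_chains`` is the
    annotated single catalytic unit, a sub-multiset of the biological unit.
    ``has_structure`` marks records with a deposited 3D structure; only those
    take part in the structural (CATH domain combination) analysis.
    """

    record_id: str
    ec_nodes: Tuple[ECNode, ...]
    chains: Tuple[ChainSequence, ...]
    domains: Tuple[DomainAssignment, ...] = ()
    residue_annotations: Tuple[ResidueAnnotation, ...] = ()
    cofactors: Tuple[CofactorAnnotation, ...] = ()
    biological_unit_chains: Tuple[str, ...] = ()
    catalytic_unit_chains: Tuple[str, ...] = ()
    has_structure: bool = True

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValidationError("record_id must be non-empty")
        if not self.ec_nodes:
            raise ValidationError(f"{self.record_id}: at least one EC node required")
        if not self.chains:
            raise ValidationError(f"{self.record_id}: at least one chain required")
        if not self.biological_unit_chains:
            object.__setattr__(
                self, "biological_unit_chains", tuple(c.chain_id for c in self.chains)
            )

    # -- resolution helpers -------------------------------------------------

    @property
    def chain_map(self) -> Mapping[str, ChainSequence]:
        return {c.chain_id: c for c in self.chains}

    def sequence_of(self, chain_id: str) -> str:
        try:
            return self.chain_map[chain_id].sequence
        except KeyError:
            raise LinkageError(f"{self.record_id}: unknown chain {chain_id!r}") from None

    @property
    def concatenated_sequence(self) -> str:
        """Chain sequences concatenated in chain-id order (clustering input)."""
        return "".join(c.sequence for c in sorted(self.chains, key=lambda c: c.chain_id))

    @property
    def complete_ec_nodes(self) -> Tuple[ECNode, ...]:
        return tuple(n for n in self.ec_nodes if n.is_complete)

    @property
    def catalytic_annotations(self) -> Tuple[ResidueAnnotation, ...]:
        return tuple(
            a for a in self.residue_annotations if a.function_context == "catalytic"
        )

    @property
    def binding_annotations(self) -> Tuple[ResidueAnnotation, ...]:
        return tuple(a for a in self.residue_annotations if a.function_context == "binding")

    def validate(self) -> None:
        """Check all cross-reference invariants; raise ``ValidationError``."""
        chain_ids = [c.chain_id for c in self.chains]
        if len(set(chain_ids)) != len(chain_ids):
            raise ValidationError(f"{self.record_id}: duplicate chain ids")
        chain_map = self.chain_map
        for dom in self.domains:
            if dom.chain_id not in chain_map:
                raise LinkageError(
                    f"{self.record_id}: domain {dom.cath_code} on unknown chain "
                    f"{dom.chain_id!r}"
                )
            length = len(chain_map[dom.chain_id])
            if dom.segments[-1][1] > length:
                raise LinkageError(
                    f"{self.record_id}: domain {dom.cath_code} segment ends at "
                    f"{dom.segments[-1][1]} but chain {dom.chain_id} has "
                    f"{length} residues"
                )
        for ann in self.residue_annotations:
            if ann.chain_id not in chain_map:
                raise LinkageError(
                    f"{self.record_id}: annotation at {ann.chain_id}:{ann.position} "
                    "references an unknown chain"
                )
            seq = chain_map[ann.chain_id].sequence
            if ann.position > len(seq):
                raise LinkageError(
                    f"{self.record_id}: annotation position {ann.position} beyond "
                    f"chain {ann.chain_id} length {len(seq)}"
                )
            letter = seq[ann.position - 1]
            if letter != ann.residue_type:
                raise LinkageError(
                    f"{self.record_id}: annotation {ann.chain_id}:{ann.position} says "
                    f"{ann.residue_type} but the sequence has {letter}"
                )
        bio = list(self.biological_unit_chains)
        for cid in bio:
            if cid not in chain_map:
                raise LinkageError(
                    f"{self.record_id}: biological unit names unknown chain {cid!r}"
                )
        remaining = list(bio)
        for cid in self.catalytic_unit_chains:
            if cid not in remaining:
                raise ValidationError(
                    f"{self.record_id}: catalytic unit chain {cid!r} not contained "
                    "in the biological unit"
                )
            remaining.remove(cid)
        if not self.catalytic_annotations and not self.cofactors:
            raise ValidationError(
                f"{self.record_id}: an enzyme needs at least one catalytic residue "
                "or cofactor"
            )


@dataclass
class Dataset:
    """A collection of enzyme records with unique ids."""

    records: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EnzymeRecord]:
        return iter(self.records)

    def get(self, record_id: str) -> EnzymeRecord:
        for record in self.records:
            if record.record_id == record_id:
                return record
        raise KeyError(record_id)

    def validate(self) -> None:
        for record in self.records:
            record.validate()

    @property
    def ec_classes(self) -> Tuple[int, ...]:
        """Sorted EC classes present (first digit of any node, complete or not)."""
        return tuple(sorted({n.class_digit for r in self.records for n in r.ec_nodes}))

    def records_of_class(self, ec_class: Optional[int]) -> list:
        """Records carrying an EC node of the given class (``None`` = all).

        A record with nodes in several classes is returned for each of them.
        """
        if ec_class is None:
            return list(self.records)
        return [
            r for r in self.records if any(n.class_digit == ec_class for n in r.ec_nodes)
        ]

    def records_of_node(self, node: ECNode) -> list:
        return [r for r in self.records if node in r.ec_nodes]

    @property
    def complete_nodes(self) -> Tuple[ECNode, ...]:
        """Sorted distinct complete EC nodes over all records."""
        return tuple(
            sorted({n for r in self.records for n in r.complete_ec_nodes})
        )


def select_complete_ec(dataset: Dataset) -> Dataset:
    """Keep only records with at least one fully assigned four-level EC node.

    Idempotent; records with several nodes are retained whole and later
    counted once under each complete node.
    """
    kept = [r for r in dataset.records if r.complete_ec_nodes]
    return Dataset(records=kept, provenance=dataset.provenance)
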