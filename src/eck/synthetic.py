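"""Synthetic MACiE-like dataset generator with planted ground truth.

The generator emulates the statistical structure of a mechanism-level enzyme
database joined to sequence and structure resources:

* per EC node, a planted number of evolutionary families; members of one
  family are mutated copies of a family founder (high within-family percent
  identity), founders of different families are unrelated (identity capped);
* catalytic residues drawn with probability proportional to
  ``background frequency x propensity multiplier`` for the record's EC class;
* seven-category functional roles drawn per catalytic entity kind, with
  hydride shuttling reserved to organic cofactors by default;
* domain architectures (single-domain, multi-domain, multi-chain, binding
  domains) drawn from a weighted pattern list shaped like the observed
  configuration census.

Everything is driven by one ``numpy`` generator seeded from the config, so a
fixed config yields byte-identical datasets.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .alignment import AlignmentParams, DEFAULT_PARAMS, global_identity
from .records import (
    AMINO_ACIDS,
    CofactorAnnotation,
    ChainSequence,
    Dataset,
    DomainAssignment,
    ECNode,
    EnzymeRecord,
    ESSENTIAL_RESIDUES,
    HYDRIDE_SHUTTLE,
    NONPOLAR_RESIDUES,
    REACTANT_ROLES,
    ResidueAnnotation,
    ROLE_CATEGORIES,
    ValidationError,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "ConfigError",
    "generate",
    "mutate_to_identity",
    "plant_sites",
    "DEFAULT_CATH_POOL",
    "DEFAULT_ARCHITECTURE_PATTERNS",
]


class ConfigError(ValueError):
    """The generator configuration is infeasible or inconsistent."""


#: CATH H-level codes the generator draws from.  The pool deliberately
#: includes a few codes famous for reuse across reactions (Rossmann fold,
#: trypsin-like protease, TIM barrel) so that domain->EC promiscuity arises.
DEFAULT_CATH_POOL: Tuple[str, ...] = (
    "3.40.50.720",
    "2.40.10.10",
    "3.20.20.70",
    "1.10.600.10",
    "3.40.50.970",
    "3.60.20.10",
    "3.40.50.10490",
    "1.10.10.10",
    "2.60.40.10",
    "3.30.200.20",
    "1.20.120.10",
    "2.30.30.40",
    "3.40.190.10",
    "1.10.510.10",
    "3.90.190.10",
    "2.160.20.10",
    "3.10.20.30",
    "1.25.40.10",
    "2.120.10.80",
    "3.50.50.60",
)

#: Architecture pattern language: chains separated by ``/``, domains within a
#: chain by ``+``; ``*`` marks a catalytic domain (hosts catalytic residues),
#: ``^`` marks a binding domain (gets three planted binding residues).  The
#: default weights follow the shape of the observed configuration census:
#: single catalytic domain with 1..4 biological-unit domains dominates, plus
#: duplicated catalytic domains and an interface enzyme whose catalytic
#: domain repeats on two chains.
DEFAULT_ARCHITECTURE_PATTERNS: Tuple[Tuple[str, float], ...] = (
    ("A*", 86.0),
    ("A*+B", 24.0),
    ("A*+B+C", 5.0),
    ("A*+B+C+D", 2.0),
    ("A*+B^", 12.0),
    ("A*+A*", 8.0),
    ("A*/A*+B", 6.0),
)

#: Default role weights per catalytic-entity kind.  Residues and metal ions
#: have hydride-shuttle weight 0 (only organic cofactors hydride-shuttle);
#: metals are biased toward stabilization and electron shuttling.
DEFAULT_ROLE_WEIGHTS: Mapping[str, Mapping[str, float]] = {
    "residue": {
        "activation": 1.0,
        "steric": 0.5,
        "stabilization": 1.5,
        "proton_shuttle": 1.5,
        "h_radical_shuttle": 0.1,
        "electron_shuttle": 0.3,
        "covalent_catalysis": 0.6,
        HYDRIDE_SHUTTLE: 0.0,
    },
    "metal_ion": {
        "activation": 1.0,
        "steric": 0.2,
        "stabilization": 2.0,
        "proton_shuttle": 0.1,
        "h_radical_shuttle": 0.05,
        "electron_shuttle": 1.5,
        "covalent_catalysis": 0.1,
        HYDRIDE_SHUTTLE: 0.0,
    },
    "organic_cofactor": {
        "activation": 0.8,
        "steric": 0.2,
        "stabilization": 0.8,
        "proton_shuttle": 0.8,
        "h_radical_shuttle": 0.4,
        "electron_shuttle": 1.2,
        "covalent_catalysis": 0.6,
        HYDRIDE_SHUTTLE: 1.0,
    },
}

#: Planted family-count distribution per EC node: about half of the nodes
#: carry a single family, mirroring the observed "almost 50% singleton
#: nodes" regime.
DEFAULT_FAMILY_COUNT_WEIGHTS: Mapping[int, float] = {1: 0.5, 2: 0.25, 3: 0.15, 4: 0.10}

IntOrRange = Union[int, Tuple[int, int]]


@dataclass
class GeneratorConfig:
    """All tunables of the synthetic dataset generator.

    ``within_family_identity`` must exceed ``between_family_identity_cap``
    for the planted families to be separable by identity-threshold
    clustering; the generation-time tolerance on realized identities is
    5 percentage points.
    """

    n_ec_nodes: int = 20
    families_per_node: Union[None, Sequence[int], Mapping[int, float]] = None
    members_per_family: IntOrRange = (2, 4)
    seq_length: IntOrRange = 150
    within_family_identity: float = 90.0
    between_family_identity_cap: float = 15.0
    propensity_multipliers: Optional[Mapping] = None
    n_catalytic_per_record: IntOrRange = 3
    background_frequencies: Optional[Mapping[str, float]] = None
    role_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ROLE_WEIGHTS.items()}
    )
    two_role_probability: float = 0.3
    architecture_patterns: Sequence[Tuple[str, float]] = DEFAULT_ARCHITECTURE_PATTERNS
    binding_residues_per_binding_domain: int = 3
    metal_cofactor_probability: float = 0.30
    organic_cofactor_probability: float = 0.25
    organic_cofactor_probability_class1: float = 0.85
    structure_probability: float = 0.5
    cath_pool: Sequence[str] = DEFAULT_CATH_POOL
    indel_rate: float = 0.0
    max_founder_retries: int = 100
    alignment_params: AlignmentParams = DEFAULT_PARAMS
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_ec_nodes < 1:
            raise ConfigError("n_ec_nodes must be >= 1")
        if self.within_family_identity <= self.between_family_identity_cap:
            raise ConfigError(
                "within_family_identity must exceed between_family_identity_cap "
                f"({self.within_family_identity} <= {self.between_family_identity_cap})"
            )
        if isinstance(self.families_per_node, Sequence) and not isinstance(
            self.families_per_node, (str, bytes)
        ):
            if len(self.families_per_node) != self.n_ec_nodes:
                raise ConfigError(
                    "explicit families_per_node list must have n_ec_nodes entries"
                )
            if any(int(k) < 1 for k in self.families_per_node):
                raise ConfigError("family counts must be >= 1")
        for kind, weights in self.role_weights.items():
            if any(w < 0 for w in weights.values()):
                raise ConfigError(f"negative role weight for {kind}")
        if self.propensity_multipliers:
            for value in _flatten_multipliers(self.propensity_multipliers):
                if value <= 0:
                    raise ConfigError("propensity multipliers must be > 0")
        if not (0 <= self.structure_probability <= 1):
            raise ConfigError("structure_probability must be in [0, 1]")

    def background_vector(self) -> np.ndarray:
        if self.background_frequencies is None:
            return np.full(20, 1.0 / 20.0)
        vec = np.array([self.background_frequencies.get(a, 0.0) for a in AMINO_ACIDS])
        if vec.sum() <= 0:
            raise ConfigError("background frequencies must sum to a positive value")
        return vec / vec.sum()

    def multiplier_vector(self, ec_class: int) -> np.ndarray:
        """Per-residue-type multipliers for one EC class, as a length-20 array."""
        if not self.propensity_multipliers:
            return np.ones(20)
        table = self.propensity_multipliers
        if all(isinstance(k, str) for k in table):
            class_table = table  # one flat table for every class
        else:
            class_table = table.get(ec_class, {})
        return np.array([float(class_table.get(a, 1.0)) for a in AMINO_ACIDS])


def _flatten_multipliers(table: Mapping) -> List[float]:
    out: List[float] = []
    for value in table.values():
        if isinstance(value, Mapping):
            out.extend(float(v) for v in value.values())
        else:
            out.append(float(value))
    return out


@dataclass
class GroundTruth:
    """Planted parameters of a generated dataset, for recovery tests."""

    family_of: Dict[str, str]
    node_family_counts: Dict[str, int]
    planted_multipliers: Dict[int, Dict[str, float]]
    planted_architecture: Dict[str, Dict[str, object]]

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as handle:
            data = json.load(handle)
        data["planted_multipliers"] = {
            int(k): v for k, v in data["planted_multipliers"].items()
        }
        return cls(**data)


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def mutate_to_identity(
    seq: str,
    target_identity_percent: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> str:
    """Return a copy of ``seq`` at the target ungapped identity.

    Substitution-only by default: ``round(L * (1 - target/100))`` positions are
    chosen without replacement and replaced by a different letter, so the
    realized Hamming identity matches the target to within rounding.  With
    ``indel_rate > 0`` each substitution event becomes a single-residue
    insertion or deletion with that probability (off by default).
    """
    if not 0 <= target_identity_percent <= 100:
        raise ValueError("target identity must be in [0, 100]")
    length = len(seq)
    n_mut = round(length * (1.0 - target_identity_percent / 100.0))
    if n_mut == 0:
        return seq
    letters = list(seq)
    positions = rng.choice(length, size=n_mut, replace=False)
    deletions: List[int] = []
    for pos in positions:
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                deletions.append(int(pos))
            else:
                extra = AMINO_ACIDS[rng.integers(20)]
                letters[pos] = letters[pos] + extra
            continue
        current = letters[pos][0] if letters[pos] else None
        choices = [a for a in AMINO_ACIDS if a != current]
        letters[pos] = choices[rng.integers(len(choices))]
    for pos in sorted(deletions, reverse=True):
        letters[pos] = ""
    return "".join(letters)


def _random_sequence(length: int, bg: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=bg)
    return "".join(AMINO_ACIDS[i] for i in idx)


# ---------------------------------------------------------------------------
# architecture patterns
# ---------------------------------------------------------------------------

_DOMAIN_TOKEN = re.compile(r"^([A-Z])([*^]?)$")


@dataclass(frozen=True)
class _PatternDomain:
    letter: str
    kind: str  # "catalytic" | "binding" | "other"


def _parse_pattern(pattern: str) -> List[List[_PatternDomain]]:
    chains: List[List[_PatternDomain]] = []
    for chain_part in pattern.split("/"):
        doms = []
        for token in chain_part.split("+"):
            m = _DOMAIN_TOKEN.match(token.strip())
            if not m:
                raise ConfigError(f"bad architecture token {token!r} in {pattern!r}")
            kind = {"*": "catalytic", "^": "binding", "": "other"}[m.group(2)]
            doms.append(_PatternDomain(m.group(1), kind))
        if not doms:
            raise ConfigError(f"empty chain in architecture pattern {pattern!r}")
        chains.append(doms)
    if not any(d.kind == "catalytic" for ch in chains for d in ch):
        raise ConfigError(f"pattern {pattern!r} has no catalytic domain")
    return chains


def _cath_sort_key(code: str) -> Tuple[int, ...]:
    return tuple(int(p) for p in code.split("."))


def _planted_signature(
    chains: List[List[_PatternDomain]], letter_codes: Mapping[str, str]
) -> Dict[str, object]:
    """Canonical catalytic-unit pattern implied by an architecture pattern.

    Computed directly from the pattern (independently of the analysis
    module): catalytic-unit domains are the catalytic and binding ones,
    sorted catalytic-first then by numeric CATH code, letters assigned in
    first-occurrence order per distinct code.
    """
    unit = [
        (letter_codes[d.letter], d.kind == "catalytic")
        for ch in chains
        for d in ch
        if d.kind in ("catalytic", "binding")
    ]
    unit.sort(key=lambda item: (not item[1], _cath_sort_key(item[0])))
    letters: Dict[str, str] = {}
    out = []
    for code, is_cat in unit:
        if code not in letters:
            letters[code] = chr(ord("A") + len(letters))
        out.append(letters[code] + ("*" if is_cat else ""))
    n_bio = sum(len(ch) for ch in chains)
    return {"pattern": "".join(out), "n_bio_domains": n_bio}


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

def plant_sites(
    record: EnzymeRecord,
    config: GeneratorConfig,
    rng: np.random.Generator,
    ec_class: Optional[int] = None,
    catalytic_domains: Optional[Sequence[DomainAssignment]] = None,
    binding_domains: Optional[Sequence[DomainAssignment]] = None,
) -> EnzymeRecord:
    """Plant catalytic (and binding) residue annotations into a record.

    Catalytic residue types are drawn with probability proportional to
    ``background frequency x multiplier`` for the record's EC class and the
    sequence letter at the chosen position is overwritten to match.  Each
    designated catalytic domain hosts at least one catalytic residue; binding
    domains receive ``binding_residues_per_binding_domain`` binding residues.
    Acting parts follow residue chemistry: the ten side-chain-essential types
    act through their side chain, nonpolar types mostly through main-chain
    N-H / C=O groups.
    """
    if not record.chains or not record.domains:
        raise ValidationError(f"{record.record_id}: plant_sites needs chains and domains")
    if ec_class is None:
        ec_class = record.ec_nodes[0].class_digit
    if catalytic_domains is None:
        catalytic_domains = list(record.domains)
    if binding_domains is None:
        binding_domains = []

    n_cat = _draw_int(config.n_catalytic_per_record, rng)
    n_cat = max(n_cat, len(catalytic_domains))

    probs = config.background_vector() * config.multiplier_vector(ec_class)
    probs = probs / probs.sum()

    sequences = {c.chain_id: list(c.sequence) for c in record.chains}
    taken = {cid: set() for cid in sequences}

    def free_positions(dom: DomainAssignment) -> List[int]:
        return [
            p
            for start, end in dom.segments
            for p in range(start, end + 1)
            if p not in taken[dom.chain_id]
        ]

    # one catalytic residue per designated domain first, then the rest spread
    # uniformly over the designated domains
    hosts = list(catalytic_domains)
    hosts += [
        catalytic_domains[rng.integers(len(catalytic_domains))]
        for _ in range(n_cat - len(catalytic_domains))
    ]
    annotations: List[ResidueAnnotation] = []
    weights = config.role_weights["residue"]
    for dom in hosts:
        positions = free_positions(dom)
        if not positions:
            raise ValidationError(
                f"{record.record_id}: domain {dom.cath_code} too short to host "
                "the requested catalytic sites"
            )
        pos = positions[rng.integers(len(positions))]
        taken[dom.chain_id].add(pos)
        aa = AMINO_ACIDS[rng.choice(20, p=probs)]
        sequences[dom.chain_id][pos - 1] = aa
        roles = _draw_roles(weights, config.two_role_probability, rng)
        annotations.append(
            ResidueAnnotation(
                chain_id=dom.chain_id,
                position=pos,
                residue_type=aa,
                function_context="catalytic",
                involvement="reactant" if roles & REACTANT_ROLES else "spectator",
                roles=roles,
                acting_part=_draw_acting_part(aa, rng),
            )
        )
    for dom in binding_domains:
        for _ in range(config.binding_residues_per_binding_domain):
            positions = free_positions(dom)
            if not positions:
                raise ValidationError(
                    f"{record.record_id}: domain {dom.cath_code} too short to host "
                    "the requested binding sites"
                )
            pos = positions[rng.integers(len(positions))]
            taken[dom.chain_id].add(pos)
            aa = sequences[dom.chain_id][pos - 1]
            annotations.append(
                ResidueAnnotation(
                    chain_id=dom.chain_id,
                    position=pos,
                    residue_type=aa,
                    function_context="binding",
                )
            )

    chains = tuple(
        ChainSequence(c.chain_id, "".join(sequences[c.chain_id])) for c in record.chains
    )
    annotations.sort(key=lambda a: (a.chain_id, a.position))
    return EnzymeRecord(
        record_id=record.record_id,
        ec_nodes=record.ec_nodes,
        chains=chains,
        domains=record.domains,
        residue_annotations=tuple(annotations),
        cofactors=record.cofactors,
        biological_unit_chains=record.biological_unit_chains,
        catalytic_unit_chains=record.catalytic_unit_chains,
        has_structure=record.has_structure,
    )


def _draw_int(value: IntOrRange, rng: np.random.Generator) -> int:
    if isinstance(value, int):
        return value
    lo, hi = value
    return int(rng.integers(lo, hi + 1))


def _draw_roles(
    weights: Mapping[str, float], two_role_probability: float, rng: np.random.Generator
) -> frozenset:
    names = [r for r in ROLE_CATEGORIES if weights.get(r, 0.0) > 0]
    w = np.array([weights[r] for r in names])
    if not names:
        raise ConfigError("residue role weights are all zero")
    k = 2 if (len(names) > 1 and rng.random() < two_role_probability) else 1
    picked = rng.choice(len(names), size=k, replace=False, p=w / w.sum())
    return frozenset(names[i] for i in np.atleast_1d(picked))


def _draw_cofactor_roles(
    weights: Mapping[str, float], two_role_probability: float, rng: np.random.Generator
) -> frozenset:
    names = [r for r in weights if weights[r] > 0]
    w = np.array([weights[r] for r in names])
    k = 2 if (len(names) > 1 and rng.random() < two_role_probability) else 1
    picked = rng.choice(len(names), size=k, replace=False, p=w / w.sum())
    return frozenset(names[i] for i in np.atleast_1d(picked))


def _draw_acting_part(aa: str, rng: np.random.Generator) -> str:
    if aa in ESSENTIAL_RESIDUES:
        return "side_chain"
    if aa in NONPOLAR_RESIDUES:
        # nonpolar residues act mainly through their main-chain N-H / C=O
        return ("main_chain_NH", "main_chain_CO", "side_chain")[
            rng.choice(3, p=[0.4, 0.4, 0.2])
        ]
    return "side_chain"


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------

def generate(config: GeneratorConfig) -> Tuple[Dataset, GroundTruth]:
    """Generate a dataset and its planted ground truth. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    bg = config.background_vector()

    nodes = _draw_ec_nodes(config.n_ec_nodes, rng)
    family_counts = _draw_family_counts(config, rng)

    patterns = [(_parse_pattern(p), w) for p, w in config.architecture_patterns]
    pattern_weights = np.array([w for _, w in patterns], dtype=float)
    if pattern_weights.sum() <= 0:
        raise ConfigError("architecture pattern weights must sum to > 0")
    pattern_weights = pattern_weights / pattern_weights.sum()

    records: List[EnzymeRecord] = []
    family_of: Dict[str, str] = {}
    node_family_counts: Dict[str, int] = {}
    planted_architecture: Dict[str, Dict[str, object]] = {}
    counter = 0

    for node, n_families in zip(nodes, family_counts):
        node_family_counts[str(node)] = n_families
        founders: List[str] = []
        for fam_idx in range(n_families):
            pattern = patterns[rng.choice(len(patterns), p=pattern_weights)][0]
            letter_codes = _assign_cath_codes(pattern, config, rng)
            chain_specs = _founder_chains(pattern, letter_codes, config, bg, rng, founders)
            founders.append("".join(seq for _, seq, _ in chain_specs))
            signature = _planted_signature(pattern, letter_codes)
            family_label = f"{node}|F{fam_idx + 1}"
            n_members = _draw_int(config.members_per_family, rng)
            member_target = (100.0 + config.within_family_identity) / 2.0
            for _ in range(n_members):
                counter += 1
                record_id = f"M{counter:05d}"
                record = _make_member(
                    record_id,
                    node,
                    chain_specs,
                    pattern,
                    member_target,
                    config,
                    rng,
                )
                records.append(record)
                family_of[record_id] = family_label
                planted_architecture[record_id] = dict(signature)

    dataset = Dataset(
        records=records,
        provenance=f"synthetic dataset, seed={config.rng_seed}, "
        f"{config.n_ec_nodes} EC nodes",
    )
    dataset.validate()
    truth = GroundTruth(
        family_of=family_of,
        node_family_counts=node_family_counts,
        planted_multipliers={
            c: {a: float(m) for a, m in zip(AMINO_ACIDS, config.multiplier_vector(c))}
            for c in range(1, 7)
        },
        planted_architecture=planted_architecture,
    )
    return dataset, truth


def _draw_ec_nodes(n: int, rng: np.random.Generator) -> List[ECNode]:
    nodes: List[ECNode] = []
    seen = set()
    serial = 0
    while len(nodes) < n:
        serial += 1
        ec_class = 1 + (len(nodes) % 6)
        code = (
            ec_class,
            int(rng.integers(1, 30)),
            int(rng.integers(1, 30)),
            serial,
        )
        if code in seen:
            continue
        seen.add(code)
        nodes.append(ECNode(*code))
    return nodes


def _draw_family_counts(config: GeneratorConfig, rng: np.random.Generator) -> List[int]:
    spec = config.families_per_node
    if spec is None:
        spec = DEFAULT_FAMILY_COUNT_WEIGHTS
    if isinstance(spec, Mapping):
        counts = np.array(sorted(spec), dtype=int)
        weights = np.array([spec[int(c)] for c in counts], dtype=float)
        weights = weights / weights.sum()
        return [int(c) for c in rng.choice(counts, size=config.n_ec_nodes, p=weights)]
    return [int(c) for c in spec]


def _assign_cath_codes(
    pattern: List[List[_PatternDomain]], config: GeneratorConfig, rng: np.random.Generator
) -> Dict[str, str]:
    letters = sorted({d.letter for ch in pattern for d in ch})
    if len(letters) > len(config.cath_pool):
        raise ConfigError("architecture pattern needs more distinct codes than the pool")
    picked = rng.choice(len(config.cath_pool), size=len(letters), replace=False)
    return {letter: config.cath_pool[i] for letter, i in zip(letters, picked)}


def _founder_chains(
    pattern: List[List[_PatternDomain]],
    letter_codes: Mapping[str, str],
    config: GeneratorConfig,
    bg: np.ndarray,
    rng: np.random.Generator,
    existing_founders: Sequence[str],
) -> List[Tuple[str, str, List[Tuple[DomainAssignment, _PatternDomain]]]]:
    """Draw founder chains for one family, respecting the between-family cap.

    Returns ``(chain_id, founder_sequence, [(domain, pattern_domain), ...])``
    per chain.  The concatenated founder is rejection-sampled until its global
    identity to every existing founder of the node is at or below the cap.
    """
    for _ in range(config.max_founder_retries):
        chain_specs = []
        for chain_idx, chain_pattern in enumerate(pattern):
            chain_id = chr(ord("A") + chain_idx)
            length = _draw_int(config.seq_length, rng)
            length = max(length, 20 * len(chain_pattern))
            seq = _random_sequence(length, bg, rng)
            bounds = np.linspace(0, length, len(chain_pattern) + 1).astype(int)
            doms = [
                (
                    DomainAssignment(
                        chain_id,
                        letter_codes[pd.letter],
                        ((int(bounds[i]) + 1, int(bounds[i + 1])),),
                    ),
                    pd,
                )
                for i, pd in enumerate(chain_pattern)
            ]
            chain_specs.append((chain_id, seq, doms))
        concatenated = "".join(seq for _, seq, _ in chain_specs)
        if all(
            global_identity(concatenated, other, config.alignment_params)[0]
            <= config.between_family_identity_cap
            for other in existing_founders
        ):
            return chain_specs
    raise ConfigError(
        "could not draw a founder below the between-family identity cap of "
        f"{config.between_family_identity_cap}% in {config.max_founder_retries} tries"
    )


def _make_member(
    record_id: str,
    node: ECNode,
    chain_specs,
    pattern: List[List[_PatternDomain]],
    member_target_identity: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> EnzymeRecord:
    chains = []
    domains: List[DomainAssignment] = []
    catalytic_domains: List[DomainAssignment] = []
    binding_domains: List[DomainAssignment] = []
    unit_chains: List[str] = []
    for chain_id, founder_seq, doms in chain_specs:
        member_seq = mutate_to_identity(
            founder_seq, member_target_identity, rng, config.indel_rate
        )
        chains.append(ChainSequence(chain_id, member_seq))
        in_unit = False
        for dom, pattern_dom in doms:
            domains.append(dom)
            if pattern_dom.kind == "catalytic":
                catalytic_domains.append(dom)
                in_unit = True
            elif pattern_dom.kind == "binding":
                binding_domains.append(dom)
                in_unit = True
        if in_unit:
            unit_chains.append(chain_id)

    record = EnzymeRecord(
        record_id=record_id,
        ec_nodes=(node,),
        chains=tuple(chains),
        domains=tuple(domains),
        biological_unit_chains=tuple(c.chain_id for c in chains),
        catalytic_unit_chains=tuple(unit_chains),
        has_structure=bool(rng.random() < config.structure_probability),
    )
    record = plant_sites(
        record,
        config,
        rng,
        ec_class=node.class_digit,
        catalytic_domains=catalytic_domains,
        binding_domains=binding_domains,
    )
    return _add_cofactors(record, config, rng)


def _add_cofactors(
    record: EnzymeRecord, config: GeneratorConfig, rng: np.random.Generator
) -> EnzymeRecord:
    ec_class = record.ec_nodes[0].class_digit
    organic_p = (
        config.organic_cofactor_probability_class1
        if ec_class == 1
        else config.organic_cofactor_probability
    )
    cofactors: List[CofactorAnnotation] = []
    if rng.random() < config.metal_cofactor_probability:
        cofactors.append(
            CofactorAnnotation(
                "MG" if rng.random() < 0.5 else "ZN",
                "metal_ion",
                _draw_cofactor_roles(
                    config.role_weights["metal_ion"], config.two_role_probability, rng
                ),
            )
        )
    if rng.random() < organic_p:
        cofactors.append(
            CofactorAnnotation(
                ("NAD", "FAD", "PLP")[rng.integers(3)],
                "organic_cofactor",
                _draw_cofactor_roles(
                    config.role_weights["organic_cofactor"], config.two_role_probability, rng
                ),
            )
        )
    if not cofactors:
        return record
    return EnzymeRecord(
        record_id=record.record_id,
        ec_nodes=record.ec_nodes,
        chains=record.chains,
        domains=record.domains,
        residue_annotations=record.residue_annotations,
        cofactors=tuple(cofactors),
        biological_unit_chains=record.biological_unit_chains,
        catalytic_unit_chains=record.catalytic_unit_chains,
        has_structure=record.has_structure,
    )
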