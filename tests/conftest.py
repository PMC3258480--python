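"""Shared fixtures: hand-built records and small synthetic corpora."""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pytest
from hypothesis import settings

from eck.records import (
    CofactorAnnotation,
    ChainSequence,
    Dataset,
    DomainAssignment,
    ECNode,
    EnzymeRecord,
    ResidueAnnotation,
    REACTANT_ROLES,
)
from eck.synthetic import GeneratorConfig, generate

settings.register_profile("eck", derandomize=True, deadline=None)
settings.load_profile("eck")


def build_record(
    record_id: str = "R1",
    ec_nodes: Sequence[str] = ("1.1.1.1",),
    chains: Optional[Mapping[str, str]] = None,
    domains: Sequence[Tuple[str, str, Sequence[Tuple[int, int]]]] = (),
    catalytic: Sequence[Tuple[str, int]] = (),
    binding: Sequence[Tuple[str, int]] = (),
    roles: Iterable[str] = ("proton_shuttle",),
    cofactors: Sequence[Tuple[str, str, Iterable[str]]] = (),
    catalytic_unit: Sequence[str] = (),
    biological_unit: Sequence[str] = (),
    has_structure: bool = True,
) -> EnzymeRecord:
    """Assemble a valid record; residue types are read off the sequences.

    ``catalytic``/``binding`` are (chain_id, 1-based position) pairs; all
    catalytic annotations share ``roles``.
    """
    if chains is None:
        chains = {"A": "ACDEFGHIKLMNPQRSTVWY" * 2}
    role_set = frozenset(roles)
    annotations = []
    for chain_id, pos in catalytic:
        annotations.append(
            ResidueAnnotation(
                chain_id=chain_id,
                position=pos,
                residue_type=chains[chain_id][pos - 1],
                function_context="catalytic",
                involvement="reactant" if role_set & REACTANT_ROLES else "spectator",
                roles=role_set,
            )
        )
    for chain_id, pos in binding:
        annotations.append(
            ResidueAnnotation(
                chain_id=chain_id,
                position=pos,
                residue_type=chains[chain_id][pos - 1],
                function_context="binding",
            )
        )
    record = EnzymeRecord(
        record_id=record_id,
        ec_nodes=tuple(ECNode.from_string(e) for e in ec_nodes),
        chains=tuple(ChainSequence(cid, seq) for cid, seq in chains.items()),
        domains=tuple(
            DomainAssignment(cid, code, tuple(segs)) for cid, code, segs in domains
        ),
        residue_annotations=tuple(annotations),
        cofactors=tuple(
            CofactorAnnotation(cid, kind, frozenset(r)) for cid, kind, r in cofactors
        ),
        biological_unit_chains=tuple(biological_unit),
        catalytic_unit_chains=tuple(catalytic_unit),
        has_structure=has_structure,
    )
    record.validate()
    return record


@pytest.fixture(scope="session")
def small_synthetic():
    """Default-condition synthetic corpus, 20 EC nodes."""
    return generate(GeneratorConfig(n_ec_nodes=20, rng_seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_synthetic) -> Dataset:
    return small_synthetic[0]
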