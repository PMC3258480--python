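"""Readers and writers for the on-disk enzyme-record formats.

Five files describe a dataset (all positions 1-based, segment ranges
inclusive):

* ``sequences.fasta`` — chain sequences, headers ``>record_id|chain_id``
* ``residues.tsv``    — catalytic/binding residue annotations
* ``domains.tsv``     — CATH H-level domain assignments
* ``cofactors.tsv``   — metal-ion / organic-cofactor annotations
* ``units.tsv``       — per-record EC nodes, unit composition, structure flag

TSV files start with a ``#`` comment line stating the indexing convention and
a tab-separated header row.  Empty cells mean "not applicable" (e.g. roles of
a binding residue).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CofactorAnnotation,
    ChainSequence,
    Dataset,
    DomainAssignment,
    ECNode,
    EnzymeRecord,
    FormatError,
    LinkageError,
    ResidueAnnotation,
)

__all__ = ["FILE_NAMES", "read_dataset", "write_dataset", "load_dataset"]

FILE_NAMES = {
    "sequences": "sequences.fasta",
    "residues": "residues.tsv",
    "domains": "domains.tsv",
    "cofactors": "cofactors.tsv",
    "units": "units.tsv",
}

_COMMENT = "# residue positions are 1-based; segment ranges are inclusive"

_COLUMNS = {
    "residues": [
        "record_id",
        "chain_id",
        "position",
        "residue_type",
        "function_context",
        "involvement",
        "roles",
        "acting_part",
    ],
    "domains": ["record_id", "chain_id", "cath_code", "segments"],
    "cofactors": ["record_id", "cofactor_id", "entity_kind", "roles"],
    "units": [
        "record_id",
        "biological_unit_chains",
        "catalytic_unit_chains",
        "ec_nodes",
        "has_structure",
    ],
}


def _read_table(path: Union[str, os.PathLike], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[kind] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def _row_label(path, idx: int) -> str:
    # +2: one for the header row, one for 0- vs 1-based counting; the
    # leading comment line written by write_dataset adds one more, which we
    # cannot know for foreign files, so the label names the data row.
    return f"{Path(path).name} data row {idx + 1}"


def read_dataset(
    sequence_file: Union[str, os.PathLike],
    residues_table: Union[str, os.PathLike],
    domains_table: Union[str, os.PathLike],
    cofactors_table: Union[str, os.PathLike],
    units_table: Union[str, os.PathLike],
    provenance: str = "",
) -> Dataset:
    """Read and cross-validate a dataset from its five files.

    The join is permissive in one direction only: a chain present in the
    FASTA but absent from every annotation table yields a record with empty
    annotations, while an annotation row referencing an unknown chain or an
    out-of-range position raises :class:`LinkageError` naming the row.
    """
    chains: Dict[str, List[ChainSequence]] = {}
    order: List[str] = []
    for rec in SeqIO.parse(str(sequence_file), "fasta"):
        if "|" not in rec.id:
            raise FormatError(
                f"{sequence_file}: FASTA header {rec.id!r} is not record_id|chain_id"
            )
        record_id, chain_id = rec.id.split("|", 1)
        if record_id not in chains:
            chains[record_id] = []
            order.append(record_id)
        chains[record_id].append(ChainSequence(chain_id, str(rec.seq).upper()))

    units = _read_table(units_table, "units")
    unit_info: Dict[str, dict] = {}
    for idx, row in units.iterrows():
        rid = row["record_id"]
        if rid in unit_info:
            raise FormatError(f"{_row_label(units_table, idx)}: duplicate record {rid}")
        try:
            nodes = tuple(
                ECNode.from_string(tok)
                for tok in row["ec_nodes"].split(";")
                if tok.strip()
            )
        except FormatError as exc:
            raise FormatError(f"{_row_label(units_table, idx)}: {exc}") from None
        unit_info[rid] = {
            "bio": tuple(t for t in row["biological_unit_chains"].split(",") if t),
            "cat": tuple(t for t in row["catalytic_unit_chains"].split(",") if t),
            "nodes": nodes,
            "has_structure": _parse_bool(row["has_structure"], units_table, idx),
        }

    residues: Dict[str, List[ResidueAnnotation]] = {}
    for idx, row in _read_table(residues_table, "residues").iterrows():
        label = _row_label(residues_table, idx)
        try:
            position = int(row["position"])
        except ValueError:
            raise FormatError(f"{label}: position {row['position']!r} not an integer") from None
        roles = frozenset(t for t in row["roles"].split(";") if t)
        try:
            ann = ResidueAnnotation(
                chain_id=row["chain_id"],
                position=position,
                residue_type=row["residue_type"],
                function_context=row["function_context"],
                involvement=row["involvement"] or None,
                roles=roles,
                acting_part=row["acting_part"] or "side_chain",
            )
        except ValueError as exc:
            raise type(exc)(f"{label}: {exc}") from None
        record_chains = {c.chain_id: c for c in chains.get(row["record_id"], [])}
        if row["record_id"] in chains:
            chain = record_chains.get(ann.chain_id)
            if chain is None:
                raise LinkageError(
                    f"{label}: record {row['record_id']} has no chain {ann.chain_id!r}"
                )
            if ann.position > len(chain):
                raise LinkageError(
                    f"{label}: position {ann.position} beyond chain "
                    f"{ann.chain_id} length {len(chain)}"
                )
            if chain.sequence[ann.position - 1] != ann.residue_type:
                raise LinkageError(
                    f"{label}: residue_type {ann.residue_type} does not match "
                    f"sequence letter {chain.sequence[ann.position - 1]}"
                )
        residues.setdefault(row["record_id"], []).append(ann)

    domains: Dict[str, List[DomainAssignment]] = {}
    for idx, row in _read_table(domains_table, "domains").iterrows():
        label = _row_label(domains_table, idx)
        segments = []
        for token in row["segments"].split(","):
            token = token.strip()
            try:
                start, end = token.split("-")
                segments.append((int(start), int(end)))
            except ValueError:
                raise FormatError(f"{label}: bad segment token {token!r}") from None
        try:
            dom = DomainAssignment(row["chain_id"], row["cath_code"], tuple(segments))
        except ValueError as exc:
            raise type(exc)(f"{label}: {exc}") from None
        domains.setdefault(row["record_id"], []).append(dom)

    cofactors: Dict[str, List[CofactorAnnotation]] = {}
    for idx, row in _read_table(cofactors_table, "cofactors").iterrows():
        label = _row_label(cofactors_table, idx)
        roles = frozenset(t for t in row["roles"].split(";") if t)
        try:
            cof = CofactorAnnotation(row["cofactor_id"], row["entity_kind"], roles)
        except ValueError as exc:
            raise type(exc)(f"{label}: {exc}") from None
        cofactors.setdefault(row["record_id"], []).append(cof)

    stray = (set(residues) | set(domains) | set(cofactors) | set(unit_info)) - set(chains)
    if stray:
        raise LinkageError(
            f"annotation tables reference record(s) with no sequences: {sorted(stray)}"
        )

    records = []
    for rid in order:
        info = unit_info.get(rid)
        if info is None:
            raise FormatError(f"record {rid!r} has sequences but no units.tsv row")
        record = EnzymeRecord(
            record_id=rid,
            ec_nodes=info["nodes"],
            chains=tuple(chains[rid]),
            domains=tuple(domains.get(rid, ())),
            residue_annotations=tuple(residues.get(rid, ())),
            cofactors=tuple(cofactors.get(rid, ())),
            biological_unit_chains=info["bio"],
            catalytic_unit_chains=info["cat"],
            has_structure=info["has_structure"],
        )
        record.validate()
        records.append(record)
    return Dataset(records=records, provenance=provenance)


def _parse_bool(token: str, path, idx: int) -> bool:
    if token.lower() in ("1", "true", "yes"):
        return True
    if token.lower() in ("0", "false", "no"):
        return False
    raise FormatError(f"{_row_label(path, idx)}: bad boolean {token!r}")


def load_dataset(directory: Union[str, os.PathLike], provenance: str = "") -> Dataset:
    """Read a dataset from a directory holding the five standard file names."""
    d = Path(directory)
    return read_dataset(
        d / FILE_NAMES["sequences"],
        d / FILE_NAMES["residues"],
        d / FILE_NAMES["domains"],
        d / FILE_NAMES["cofactors"],
        d / FILE_NAMES["units"],
        provenance=provenance,
    )


def write_dataset(dataset: Dataset, directory: Union[str, os.PathLike]) -> Dict[str, Path]:
    """Write the five files; ``load_dataset`` on the result round-trips.

    Output is byte-stable: rows follow dataset order and all set-valued
    fields are serialized sorted.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {key: d / name for key, name in FILE_NAMES.items()}

    seq_records = [
        SeqRecord(Seq(chain.sequence), id=f"{r.record_id}|{chain.chain_id}", description="")
        for r in dataset
        for chain in r.chains
    ]
    with open(paths["sequences"], "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")

    res_rows = [
        {
            "record_id": r.record_id,
            "chain_id": a.chain_id,
            "position": a.position,
            "residue_type": a.residue_type,
            "function_context": a.function_context,
            "involvement": a.involvement or "",
            "roles": ";".join(sorted(a.roles)),
            "acting_part": a.acting_part,
        }
        for r in dataset
        for a in r.residue_annotations
    ]
    dom_rows = [
        {
            "record_id": r.record_id,
            "chain_id": dom.chain_id,
            "cath_code": dom.cath_code,
            "segments": ",".join(f"{s}-{e}" for s, e in dom.segments),
        }
        for r in dataset
        for dom in r.domains
    ]
    cof_rows = [
        {
            "record_id": r.record_id,
            "cofactor_id": c.cofactor_id,
            "entity_kind": c.entity_kind,
            "roles": ";".join(sorted(c.roles)),
        }
        for r in dataset
        for c in r.cofactors
    ]
    unit_rows = [
        {
            "record_id": r.record_id,
            "biological_unit_chains": ",".join(r.biological_unit_chains),
            "catalytic_unit_chains": ",".join(r.catalytic_unit_chains),
            "ec_nodes": ";".join(str(n) for n in r.ec_nodes),
            "has_structure": str(r.has_structure).lower(),
        }
        for r in dataset
    ]
    for kind, rows in (
        ("residues", res_rows),
        ("domains", dom_rows),
        ("cofactors", cof_rows),
        ("units", unit_rows),
    ):
        df = pd.DataFrame(rows, columns=_COLUMNS[kind])
        with open(paths[kind], "w") as handle:
            handle.write(_COMMENT + "\n")
            df.to_csv(handle, sep="\t", index=False)
    return paths
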