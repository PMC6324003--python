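"""Minimal structure ingestion: construct sequences, observed residues, segments.

Two dialects are read:

* ``pdb-min`` — fixed-column PDB ``SEQRES`` + ``ATOM`` records; presence of a
  CA atom defines an *observed* residue.
* ``mmcif-min`` — only the ``_entity_poly_seq`` and ``_atom_site`` mmCIF
  categories.

Coordinates themselves are never kept: a chain reduces to its construct
(SEQRES-role) sequence plus per-residue author numbering and observed flags.
Author numbering is carried verbatim and never used arithmetically, except
that residues missing from the coordinate records (which therefore have no
author number in the file) get one extrapolated by seqres offset from the
nearest observed residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import gemmi

from .errors import ConsistencyError, InvalidInputError, ParseError

logger = logging.getLogger("siftsforge")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
# parent-residue table for common modified residues; anything else becomes X
MODIFIED_PARENT = {
    "MSE": "M", "SEC": "U", "CSO": "C", "PTR": "Y", "SEP": "S",
    "TPO": "T", "HYP": "P", "MLY": "K", "PCA": "E",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"


def three_to_one(name: str) -> str:
    name = name.strip().upper()
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    return MODIFIED_PARENT.get(name, "X")


@dataclass(frozen=True, slots=True)
class ResidueRef:
    """One construct residue: author numbering plus its 1-based SEQRES index."""

    chain_id: str
    author_number: int
    insertion_code: str
    seqres_index: int
    observed: bool


@dataclass(frozen=True, slots=True)
class ChainModel:
    """One polypeptide chain of a structure entry."""

    entry_id: str
    chain_id: str
    construct_sequence: str
    residues: tuple[ResidueRef, ...]

    def __post_init__(self) -> None:
        n = len(self.construct_sequence)
        seen_idx: set[int] = set()
        seen_auth: set[tuple[int, str]] = set()
        prev = 0
        for r in self.residues:
            if not (1 <= r.seqres_index <= n):
                raise ConsistencyError(
                    f"{self.entry_id}/{self.chain_id}: seqres_index {r.seqres_index} "
                    f"outside construct of length {n}"
                )
            if r.seqres_index <= prev:
                raise ConsistencyError(
                    f"{self.entry_id}/{self.chain_id}: residues not strictly "
                    "ordered by seqres_index"
                )
            prev = r.seqres_index
            seen_idx.add(r.seqres_index)
            key = (r.author_number, r.insertion_code)
            if key in seen_auth:
                raise ConsistencyError(
                    f"{self.entry_id}/{self.chain_id}: duplicate author number "
                    f"{r.author_number}{r.insertion_code!r}"
                )
            seen_auth.add(key)

    def residue_at(self, seqres_index: int) -> ResidueRef:
        for r in self.residues:
            if r.seqres_index == seqres_index:
                return r
        raise InvalidInputError(
            f"{self.entry_id}/{self.chain_id}: no residue at seqres index {seqres_index}"
        )


def observed_segments(chain: ChainModel) -> list[tuple[int, int]]:
    """Maximal runs of observed residues as 1-based inclusive (start, end) pairs."""
    segs: list[tuple[int, int]] = []
    start = prev = None
    for r in chain.residues:
        if not r.observed:
            continue
        if start is None:
            start = prev = r.seqres_index
        elif r.seqres_index == prev + 1:
            prev = r.seqres_index
        else:
            segs.append((start, prev))
            start = prev = r.seqres_index
    if start is not None:
        segs.append((start, prev))
    return segs


def _build_residues(
    chain_id: str,
    n: int,
    observed: dict[int, tuple[int, str]],
) -> tuple[ResidueRef, ...]:
    """All construct positions 1..n; unobserved author numbers extrapolated."""
    obs_idx = sorted(observed)
    out = []
    for idx in range(1, n + 1):
        if idx in observed:
            num, icode = observed[idx]
            out.append(ResidueRef(chain_id, num, icode, idx, True))
        else:
            below = [i for i in obs_idx if i < idx]
            above = [i for i in obs_idx if i > idx]
            if below:
                ref = below[-1]
                num = observed[ref][0] + (idx - ref)
            elif above:
                ref = above[0]
                num = observed[ref][0] - (ref - idx)
            else:
                num = idx
            out.append(ResidueRef(chain_id, num, "", idx, False))
    return tuple(out)


def _check_residue_name(entry_id: str, chain_id: str, idx: int,
                        name: str, construct: str) -> None:
    letter = three_to_one(name)
    expected = construct[idx - 1]
    if letter != "X" and expected != "X" and letter != expected:
        raise ConsistencyError(
            f"{entry_id}/{chain_id}: coordinate residue {name} at seqres index "
            f"{idx} disagrees with construct residue {expected}"
        )


def _assign_seqres_indices(
    entry_id: str,
    chain_id: str,
    modelled: list[tuple[str, int, str]],  # (one-letter, author_number, icode)
    construct: str,
) -> list[int]:
    """Deterministic seqres-index assignment for modelled residues.

    Anchored at the smallest feasible start position, subsequent indices
    follow author-number deltas (insertion-coded residues advance by one),
    so unmodelled gaps in the construct are mirrored by gaps in author
    numbering.  Infeasible numbering or residue letters disagreeing with the
    construct raise a consistency error.
    """
    n = len(construct)

    def letter_ok(letter: str, idx: int) -> bool:
        c = construct[idx - 1]
        return letter == c or letter == "X" or c == "X"

    first_letter = modelled[0][0]
    for start in range(1, n + 1):
        if not letter_ok(first_letter, start):
            continue
        labels = [start]
        ok = True
        for (letter, num, icode), (_, pnum, picode) in zip(modelled[1:], modelled):
            if icode and num == pnum:
                delta = 1
            elif not icode and not picode:
                delta = num - pnum
            else:
                delta = 1
            idx = labels[-1] + delta
            if delta < 1 or idx > n or not letter_ok(letter, idx):
                ok = False
                break
            labels.append(idx)
        if ok:
            return labels
    raise ConsistencyError(
        f"{entry_id}/{chain_id}: coordinate residues cannot be reconciled "
        "with the construct sequence (residue name mismatch or inconsistent "
        "author numbering)"
    )


def _read_pdb_min(path: Path) -> list[ChainModel]:
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    info = dict(st.info)
    entry_id = (info.get("_entry.id") or st.name or path.stem)[:4].lower()
    st.setup_entities()
    chains: list[ChainModel] = []
    if len(st) == 0:
        raise ParseError(f"{path}: no model records")
    for ch in st[0]:
        polymer = ch.get_polymer()
        ptype = polymer.check_polymer_type() if polymer else None
        if ptype not in (gemmi.PolymerType.PeptideL, gemmi.PolymerType.PeptideD):
            logger.info("skipping non-polypeptide chain %s in %s", ch.name, path)
            continue
        entity = st.get_entity_of(polymer)
        if entity is not None and entity.full_sequence:
            seq3 = [gemmi.Entity.first_mon(m) for m in entity.full_sequence]
        else:  # no SEQRES: fall back to modelled residues
            seq3 = [r.name for r in polymer]
        construct = "".join(three_to_one(m) for m in seq3)
        modelled = [
            (three_to_one(res.name), res.seqid.num, res.seqid.icode.strip())
            for res in ch
        ]
        labels = _assign_seqres_indices(entry_id, ch.name, modelled, construct)
        observed: dict[int, tuple[int, str]] = {}
        for res, idx in zip(ch, labels):
            _check_residue_name(entry_id, ch.name, idx, res.name, construct)
            has_ca = any(atom.name == "CA" for atom in res)
            if has_ca and idx not in observed:  # first wins on alt duplicates
                observed[idx] = (res.seqid.num, res.seqid.icode.strip())
        chains.append(ChainModel(
            entry_id=entry_id,
            chain_id=ch.name,
            construct_sequence=construct,
            residues=_build_residues(ch.name, len(construct), observed),
        ))
    if not chains:
        raise ParseError(f"{path}: no polypeptide chains found")
    return chains


def _read_mmcif_min(path: Path) -> list[ChainModel]:
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    entry_id = block.name.lower()

    entity_seq: dict[str, dict[int, str]] = {}
    tab = block.find("_entity_poly_seq.", ["entity_id", "num", "mon_id"])
    for row in tab:
        entity_seq.setdefault(row[0], {})[int(row[1])] = row[2]
    if not entity_seq:
        raise ParseError(f"{path}: no _entity_poly_seq category")

    cols = ["label_atom_id", "label_comp_id", "auth_asym_id", "label_entity_id",
            "label_seq_id", "auth_seq_id", "pdbx_PDB_ins_code"]
    atoms = block.find("_atom_site.", cols)
    if not atoms:
        raise ParseError(f"{path}: no _atom_site category")

    chain_entity: dict[str, str] = {}
    chain_obs: dict[str, dict[int, tuple[int, str]]] = {}
    chain_names: dict[str, dict[int, str]] = {}
    for row in atoms:
        chain_id = row[2]
        chain_entity.setdefault(chain_id, row[3])
        if row[4] in (".", "?"):
            raise ConsistencyError(
                f"{entry_id}/{chain_id}: _atom_site row without label_seq_id"
            )
        idx = int(row[4])
        icode = "" if row[6] in (".", "?") else row[6]
        chain_names.setdefault(chain_id, {})[idx] = row[1]
        if row[0] == "CA":
            chain_obs.setdefault(chain_id, {}).setdefault(idx, (int(row[5]), icode))

    chains = []
    for chain_id in sorted(chain_entity):
        ent = chain_entity[chain_id]
        if ent not in entity_seq:
            raise ConsistencyError(
                f"{entry_id}/{chain_id}: entity {ent!r} has no _entity_poly_seq rows"
            )
        seq_map = entity_seq[ent]
        construct = "".join(three_to_one(seq_map[i]) for i in sorted(seq_map))
        for idx, name in sorted(chain_names.get(chain_id, {}).items()):
            if idx < 1 or idx > len(construct):
                raise ConsistencyError(
                    f"{entry_id}/{chain_id}: label_seq_id {idx} outside construct"
                )
            _check_residue_name(entry_id, chain_id, idx, name, construct)
        chains.append(ChainModel(
            entry_id=entry_id,
            chain_id=chain_id,
            construct_sequence=construct,
            residues=_build_residues(chain_id, len(construct),
                                     chain_obs.get(chain_id, {})),
        ))
    return chains


def read_structure_chains(path: Union[str, Path], dialect: str = "pdb-min") -> list[ChainModel]:
    """Read polypeptide chains from a structure file.

    ``dialect`` is ``pdb-min`` (fixed-column SEQRES/ATOM) or ``mmcif-min``
    (``_entity_poly_seq`` + ``_atom_site`` only).  Unknown residue names map
    to X; modified residues map to their parent residue where tabulated.
    """
    if dialect not in ("pdb-min", "mmcif-min"):
        raise InvalidInputError(f"unknown structure dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if dialect == "pdb-min":
        return _read_pdb_min(path)
    return _read_mmcif_min(path)


def write_pdb_min(chains: Iterable[ChainModel], path: Union[str, Path],
                  entry_id: str | None = None) -> None:
    """Write chains as a pdb-min file (SEQRES + one CA ATOM per observed residue).

    Coordinates are synthetic (an extended-chain placeholder); only the
    bookkeeping columns matter to the reader.
    """
    chains = list(chains)
    if not chains:
        raise InvalidInputError("no chains to write")
    entry = (entry_id or chains[0].entry_id).upper()[:4]
    lines = [f"HEADER    {'PROTEIN':<40s}{'01-JAN-00':<9s}   {entry:<4s}"]
    for chain in chains:
        res3 = [ONE_TO_THREE.get(c, "UNK") for c in chain.construct_sequence]
        for i in range(0, len(res3), 13):
            ser = i // 13 + 1
            names = " ".join(res3[i:i + 13])
            lines.append(
                f"SEQRES {ser:>3d} {chain.chain_id:1s} {len(res3):>4d}  {names}"
            )
    serial = 0
    for chain in chains:
        for r in chain.residues:
            if not r.observed:
                continue
            serial += 1
            name = ONE_TO_THREE.get(chain.construct_sequence[r.seqres_index - 1], "UNK")
            x = 3.8 * r.seqres_index
            icode = r.insertion_code or " "
            lines.append(
                f"ATOM  {serial:>5d}  CA  {name:>3s} {chain.chain_id:1s}"
                f"{r.author_number:>4d}{icode:1s}   "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{20.0:6.2f}           C"
            )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
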