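"""File I/O for traced neuron skeletons.

Two on-disk representations are supported:

* a **PDB-dialect** fixed-column coordinate format, as written by
  interactive tracing tools that re-purpose the Protein Data Bank layout
  for neuron models.  The dialect used here is documented below and is
  deliberately minimal: it carries geometry, radii and trace grouping,
  nothing else.
* the standard 7-column **SWC** neuron-morphology format, read and
  written for interoperability.  SWC encodes a parent-pointer tree; on
  reading, the tree is split into unbranched polyline traces at branch
  points (the junction node is duplicated into each child trace so each
  trace is an independent open curve).

PDB dialect
-----------
One chain per trace.  Nodes are consecutive ``ATOM`` records whose
residue sequence number is the 1-based node order within the trace.  The
x/y/z columns are interpreted directly as micrometres (no ångström
conversion), at the format's fixed 3-decimal precision.  The node radius
(μm) is stored in the occupancy column (2-decimal precision).  The
residue name encodes the constituent kind (``NEU``/``SOM``/``OTH``), the
dataset label lives on a ``TITLE`` record, and traces are separated by
``TER`` records.  Chain identifiers cycle through A–Z, a–z, 0–9 and are
cosmetic: trace boundaries are defined by ``TER``/chain change, never by
chain-id reuse.

The mapping is configurable through :class:`PdbDialect` because tracing
tools differ in which spare column they use for the radius.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (
    CaseRecord,
    ConstituentKind,
    NeuriteTrace,
    SkeletonModel,
    SkeletonNode,
    ValidationError,
    validate_model,
)

__all__ = [
    "PdbDialect",
    "ParseError",
    "read_pdb_skeleton",
    "write_pdb_skeleton",
    "read_swc",
    "write_swc",
    "read_cohort_csv",
    "write_cohort_csv",
]

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

_KIND_TO_RESNAME = {
    ConstituentKind.NEURITE: "NEU",
    ConstituentKind.SOMA: "SOM",
    ConstituentKind.OTHER: "OTH",
}
_RESNAME_TO_KIND = {v: k for k, v in _KIND_TO_RESNAME.items()}

# SWC structure-type codes: 1 = soma, 2-4 = axon/dendrite (all neurite
# here), everything else = other.
_SWC_SOMA = 1
_SWC_NEURITE_CODES = (2, 3, 4)


class ParseError(ValueError):
    """Malformed record in a skeleton file; names the offending line."""


@dataclass(frozen=True)
class PdbDialect:
    """Column mapping options for the PDB skeleton dialect.

    ``radius_field`` selects where the node radius is stored:
    ``"occupancy"`` (columns 55-60, 2 decimals, the default) or
    ``"bfactor"`` (columns 61-66).  ``coordinate_unit_scale`` multiplies
    raw coordinates on read (1.0 = file already in μm).
    """

    radius_field: str = "occupancy"
    coordinate_unit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_field not in ("occupancy", "bfactor"):
            raise ValueError(f"unknown radius_field {self.radius_field!r}")
        if self.coordinate_unit_scale <= 0:
            raise ValueError("coordinate_unit_scale must be > 0")


def _parse_atom_line(line: str, lineno: int, dialect: PdbDialect) -> tuple[str, int, int, str, float, float, float, float]:
    """Parse one fixed-column ATOM/HETATM record.

    Returns (resname, serial, resseq, chain, x, y, z, radius).
    """
    if len(line.rstrip("\n")) < 60:
        raise ParseError(f"line {lineno}: ATOM record shorter than 60 columns")
    try:
        serial = int(line[6:11])
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occupancy = float(line[54:60])
        bfactor = float(line[60:66]) if len(line.rstrip("\n")) >= 66 else 0.0
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed fixed-column field ({exc})") from None
    radius = occupancy if dialect.radius_field == "occupancy" else bfactor
    s = dialect.coordinate_unit_scale
    return resname, serial, resseq, chain, x * s, y * s, z * s, radius


def read_pdb_skeleton(
    path: Union[str, Path],
    dialect: Optional[PdbDialect] = None,
) -> SkeletonModel:
    """Read a PDB-dialect skeleton file into a :class:`SkeletonModel`.

    Traces are delimited by ``TER`` records or by a change of chain
    identifier; within a trace, nodes keep file order (the residue
    sequence number is checked to be strictly increasing).  The model is
    validated on return.

    Raises :class:`ParseError` on malformed fixed-column lines and
    :class:`~neurocurve.model.ValidationError` when the parsed model
    breaks an invariant (trace with < 2 nodes, duplicate node id,
    nonpositive radius, coincident consecutive nodes).
    """
    path = Path(path)
    dialect = dialect or PdbDialect()
    dataset_id = path.stem

    traces: list[NeuriteTrace] = []
    current_nodes: list[SkeletonNode] = []
    current_kind: Optional[ConstituentKind] = None
    current_chain: Optional[str] = None
    last_resseq: Optional[int] = None

    def flush() -> None:
        nonlocal current_nodes, current_kind, last_resseq
        if current_nodes:
            traces.append(NeuriteTrace(
                trace_id=f"T{len(traces):04d}",
                nodes=current_nodes,
                kind=current_kind or ConstituentKind.NEURITE,
            ))
        current_nodes = []
        current_kind = None
        last_resseq = None

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("TITLE"):
                title = line[6:].strip()
                if title:
                    dataset_id = title
            elif rec in ("ATOM  ", "HETATM"):
                resname, serial, resseq, chain, x, y, z, radius = _parse_atom_line(
                    line, lineno, dialect)
                kind = _RESNAME_TO_KIND.get(resname, ConstituentKind.OTHER)
                if current_nodes and (chain != current_chain):
                    flush()
                if last_resseq is not None and resseq <= last_resseq:
                    raise ParseError(
                        f"line {lineno}: residue sequence number {resseq} not "
                        f"increasing within chain {chain!r}")
                current_nodes.append(SkeletonNode(serial, x, y, z, radius))
                current_kind = kind
                current_chain = chain
                last_resseq = resseq
            elif rec.startswith("TER"):
                flush()
            # other record types (REMARK, END, ...) are ignored
    flush()

    model = SkeletonModel(dataset_id=dataset_id, traces=traces)
    violations = validate_model(model)
    if violations:
        raise ValidationError(
            f"{path}: invalid skeleton model:\n" +
            "\n".join(str(v) for v in violations))
    return model


def _format_atom_line(serial: int, kind: ConstituentKind, chain: str,
                      resseq: int, x: float, y: float, z: float,
                      radius: float, dialect: PdbDialect) -> str:
    for label, v in (("x", x), ("y", y), ("z", z)):
        if not (-999.999 <= v <= 9999.999):
            raise ValueError(
                f"coordinate {label}={v} μm not representable in an 8.3 column")
    if not (0.005 <= radius <= 999.99):
        raise ValueError(
            f"radius {radius} μm not representable in the 6.2 radius column "
            "(would round to ≤ 0 or overflow)")
    occ, bf = (radius, 0.0) if dialect.radius_field == "occupancy" else (0.0, radius)
    resname = _KIND_TO_RESNAME[kind]
    return (f"ATOM  {serial:5d}  C   {resname} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}\n")


def write_pdb_skeleton(
    model: SkeletonModel,
    path: Union[str, Path],
    dialect: Optional[PdbDialect] = None,
) -> None:
    """Write *model* in the PDB skeleton dialect.

    The output re-reads to an equivalent model: same trace partition and
    kinds, coordinates equal at the 0.001 μm column precision, radii at
    0.01 μm.  Values that cannot be represented in the fixed columns
    raise instead of being silently truncated.  An empty model yields a
    header-only file.
    """
    path = Path(path)
    dialect = dialect or PdbDialect()
    violations = validate_model(model)
    if violations:
        raise ValidationError(
            "refusing to write invalid model:\n" + "\n".join(map(str, violations)))

    lines = [f"TITLE {model.dataset_id}\n",
             "REMARK neuron skeleton trace model; coordinates in um; "
             f"radius in {dialect.radius_field} column\n"]
    serial = 0
    for i, trace in enumerate(model.traces):
        chain = _CHAIN_IDS[i % len(_CHAIN_IDS)]
        for resseq, node in enumerate(trace.nodes, start=1):
            serial += 1
            if serial > 99999:
                raise ValueError("model exceeds 99999 nodes; not representable")
            lines.append(_format_atom_line(
                serial, trace.kind, chain, resseq,
                node.x / dialect.coordinate_unit_scale,
                node.y / dialect.coordinate_unit_scale,
                node.z / dialect.coordinate_unit_scale,
                node.radius, dialect))
        lines.append(f"TER   {serial + 1:5d}\n")
        serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))


# ---------------------------------------------------------------------------
# SWC


def read_swc(path: Union[str, Path]) -> SkeletonModel:
    """Read an SWC file, splitting the tree into unbranched traces.

    SWC rows are ``id type x y z radius parent`` with ``parent = -1`` at
    roots.  The parent-pointer forest is cut at branch points: every
    maximal unbranched path from a root or branch node to the next branch
    node or leaf becomes one :class:`NeuriteTrace`, and branch nodes are
    duplicated into each child trace.  Node ids are renumbered
    sequentially so duplicated junction nodes stay unique.

    Raises :class:`ParseError` for malformed rows, orphan nodes (parent
    id that does not exist) and cyclic parent pointers.
    """
    path = Path(path)
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(f"line {lineno}: expected 7 SWC columns, got {len(parts)}")
            try:
                nid = int(parts[0]); typ = int(parts[1])
                x, y, z, r = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            if nid in rows:
                raise ParseError(f"line {lineno}: duplicate SWC node id {nid}")
            rows[nid] = (typ, x, y, z, r, parent)
            order.append(nid)

    children: dict[int, list[int]] = {nid: [] for nid in rows}
    roots: list[int] = []
    for nid in order:
        parent = rows[nid][5]
        if parent == -1:
            roots.append(nid)
        elif parent not in rows:
            raise ParseError(f"SWC node {nid}: orphan (parent {parent} does not exist)")
        else:
            children[parent].append(nid)

    # cycle check: every node must be reachable from a root
    reachable: set[int] = set()
    stack = list(roots)
    while stack:
        nid = stack.pop()
        if nid in reachable:
            raise ParseError(f"SWC node {nid}: cyclic parent pointers")
        reachable.add(nid)
        stack.extend(children[nid])
    if len(reachable) != len(rows):
        missing = sorted(set(rows) - reachable)
        raise ParseError(f"SWC nodes {missing[:5]} are in a parent-pointer cycle")

    def kind_of(typ: int) -> ConstituentKind:
        if typ == _SWC_SOMA:
            return ConstituentKind.SOMA
        if typ in _SWC_NEURITE_CODES:
            return ConstituentKind.NEURITE
        return ConstituentKind.OTHER

    traces: list[NeuriteTrace] = []
    next_id = 1

    def make_node(nid: int) -> SkeletonNode:
        nonlocal next_id
        typ, x, y, z, r, _ = rows[nid]
        node = SkeletonNode(next_id, x, y, z, r)
        next_id += 1
        return node

    # walk each maximal unbranched path starting at roots and branch nodes
    starts: list[tuple[int, Optional[int]]] = [(r, None) for r in roots]
    while starts:
        head, lead_in = starts.pop(0)
        path_ids: list[int] = [lead_in] if lead_in is not None else []
        cur = head
        while True:
            path_ids.append(cur)
            ch = children[cur]
            if len(ch) == 1 and rows[ch[0]][0] == rows[cur][0]:
                cur = ch[0]
            elif len(ch) == 1:
                # structure-type change (e.g. soma -> neurite): cut the
                # path here and start a fresh trace of the new kind
                starts.append((ch[0], None))
                break
            else:
                if len(ch) > 1:  # branch: children start new traces sharing cur
                    starts.extend((c, cur) for c in ch)
                break
        if len(path_ids) >= 2:
            typ = rows[path_ids[-1]][0]
            traces.append(NeuriteTrace(
                trace_id=f"T{len(traces):04d}",
                nodes=[make_node(nid) for nid in path_ids],
                kind=kind_of(typ)))

    model = SkeletonModel(dataset_id=path.stem, traces=traces)
    violations = validate_model(model)
    if violations:
        raise ValidationError(
            f"{path}: invalid skeleton model:\n" + "\n".join(map(str, violations)))
    return model


def write_swc(model: SkeletonModel, path: Union[str, Path]) -> None:
    """Write *model* as SWC, one root per trace (no tree re-joining).

    Each trace becomes an independent unbranched path whose first node has
    parent -1; constituent kinds map to SWC type codes (soma → 1,
    neurite → 3, other → 0).  Geometry round-trips exactly at the printed
    precision (17 significant digits, i.e. bit-exact for doubles).
    """
    path = Path(path)
    kind_code = {ConstituentKind.SOMA: 1, ConstituentKind.NEURITE: 3,
                 ConstituentKind.OTHER: 0}
    lines = [f"# SWC export of skeleton dataset {model.dataset_id}\n",
             "# id type x y z radius parent\n"]
    nid = 0
    for trace in model.traces:
        parent = -1
        for node in trace.nodes:
            nid += 1
            lines.append(f"{nid} {kind_code[trace.kind]} "
                         f"{node.x:.17g} {node.y:.17g} {node.z:.17g} "
                         f"{node.radius:.17g} {parent}\n")
            parent = nid
    path.write_text("".join(lines))


# ---------------------------------------------------------------------------
# Cohort metadata CSV

_COHORT_COLUMNS = ["case_id", "group", "age", "sex", "hallucination_score", "cpz_dose"]


def read_cohort_csv(path: Union[str, Path]) -> list[CaseRecord]:
    """Read cohort metadata (case_id,group,age,sex,hallucination_score,cpz_dose)."""
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: cohort CSV missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        dose = getattr(row, "cpz_dose", None)
        if dose is not None and (isinstance(dose, float) and math.isnan(dose)):
            dose = None
        records.append(CaseRecord(
            case_id=str(row.case_id), group=str(row.group), age=float(row.age),
            sex=str(row.sex), hallucination_score=float(row.hallucination_score),
            cpz_dose=None if dose is None else float(dose)))
    return records


def write_cohort_csv(records: list[CaseRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame([{
        "case_id": r.case_id, "group": r.group, "age": r.age, "sex": r.sex,
        "hallucination_score": r.hallucination_score,
        "cpz_dose": r.cpz_dose if r.cpz_dose is not None else "",
    } for r in records], columns=_COHORT_COLUMNS)
    df.to_csv(path, index=False)
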