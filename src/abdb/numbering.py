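"""Variable-domain numbering under the Kabat, Chothia and Martin schemes.

Numbering is implemented as profile alignment of a query sequence against a
per-role template whose columns carry the canonical position labels (light
1..107; heavy 1..82, 82A-C, 83..113).  Within each hypervariable region the
alignment's internal gap placement is discarded and residues are relabelled
deterministically around the scheme's insertion anchor, which is where the
three schemes differ (e.g. extra CDR-L1 residues become 27A, 27B... under
Kabat but 30A, 30B... under Chothia/Martin).  Residues beyond the last
variable-domain position (the constant domain) and before the first aligned
position (leader peptides) are trimmed.

Numbering fails cleanly — returning ``None`` rather than a wrong labelling —
when fewer than half of the conserved framework anchor residues match the
template.  A failed chain causes the whole entry to be rejected downstream;
no entry is ever partially numbered.
"""
from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from . import pdbio
from .chain_id import _sanitize

SCHEMES = ("kabat", "chothia", "martin")


class NumberingFailure(Exception):
    """A residue of the structure could not be mapped onto the numbering."""


@dataclass(frozen=True)
class NumberedResidue:
    role: str            # L | H
    number: int
    insertion: str       # "" or single letter
    aa: str
    seq_index: int       # index into the sequence given to number_chain

    @property
    def label(self) -> str:
        return f"{self.role}{self.number}{self.insertion}"


@dataclass
class NumberedChain:
    role: str
    scheme: str
    residues: list  # list[NumberedResidue], in position order
    source_chain_label: str = ""
    source: str = "atom"  # atom | seqres

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def labels(self) -> list:
        return [r.label for r in self.residues]


@dataclass
class SchemeTable:
    base: dict            # role -> [(num, ins), ...] ordered canonical positions
    template: dict        # role -> template sequence (one residue per base position)
    regions: dict         # role -> [(name, start_num, end_num)]
    insertion_anchors: dict  # scheme -> role -> {region name: anchor num}
    cdr_definitions: dict    # definition -> role -> {cdr name: (start, end)}
    anchors: dict            # role -> [conserved framework position numbers]
    base_index: dict = field(init=False)

    def __post_init__(self):
        self.base_index = {role: {lab: i for i, lab in enumerate(labels)}
                           for role, labels in self.base.items()}
        for role in self.base:
            if len(self.template[role]) != len(self.base[role]):
                raise ValueError(f"template/{role} length mismatch with base labels")

    def region_of(self, role: str, num: int) -> str:
        for name, start, end in self.regions[role]:
            if start <= num <= end:
                return name
        raise ValueError(f"position {role}{num} outside the variable domain")

    def max_num(self, role: str) -> int:
        return max(n for n, _ in self.base[role])


def _expand_labels(spec: list) -> list:
    out = []
    for item in spec:
        m = re.fullmatch(r"(\d+)-(\d+)", str(item))
        if m:
            out.extend((n, "") for n in range(int(m.group(1)), int(m.group(2)) + 1))
        else:
            m = re.fullmatch(r"(\d+)([A-Z]?)", str(item))
            if not m:
                raise ValueError(f"bad base label {item!r}")
            out.append((int(m.group(1)), m.group(2)))
    return out


def _read_fasta(name: str) -> str:
    text = resources.files("abdb.data").joinpath(name).read_text()
    return "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))


@functools.lru_cache(maxsize=1)
def load_scheme_table() -> SchemeTable:
    raw = yaml.safe_load(resources.files("abdb.data").joinpath("schemes.yaml").read_text())
    base = {role: _expand_labels(spec) for role, spec in raw["base_labels"].items()}
    template = {"L": _read_fasta("consensus_light.fasta"),
                "H": _read_fasta("consensus_heavy.fasta")}
    regions = {role: [(r["name"], r["start"], r["end"]) for r in rs]
               for role, rs in raw["regions"].items()}
    cdrs = {d: {role: {k: tuple(v) for k, v in m.items()}
                for role, m in roles.items()}
            for d, roles in raw["cdr_definitions"].items()}
    return SchemeTable(base=base, template=template, regions=regions,
                       insertion_anchors=raw["insertion_anchors"],
                       cdr_definitions=cdrs, anchors=raw["anchors"])


def _template_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    a.mode = "global"
    _free_end_gaps(a)
    return a


def _free_end_gaps(a: Align.PairwiseAligner) -> None:
    try:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align naming
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0


def _align_to_template(query: str, template: str):
    """(t_to_q mapping, insertions {template index -> [query indices]}) or None.

    Query residues falling before the first aligned block (leader) or after
    the last (constant domain) are simply absent from both structures.
    """
    aligner = _template_aligner()
    try:
        aln = aligner.align(template, query)[0]
    except (IndexError, ValueError):
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    t_to_q: dict = {}
    insertions: dict = {}
    prev_te = prev_qe = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_te is not None and qs > prev_qe and prev_te > 0:
            insertions.setdefault(prev_te - 1, []).extend(range(prev_qe, qs))
        for k in range(te - ts):
            t_to_q[ts + k] = qs + k
        prev_te, prev_qe = te, qe
    return t_to_q, insertions


def _next_insertion_letter(num: int, taken: set) -> str:
    for i in range(26):
        letter = chr(ord("A") + i)
        if (num, letter) not in taken:
            return letter
    raise NumberingFailure(f"more than 26 insertions at position {num}")


def number_chain(seq: str, role: str, scheme: str,
                 table: SchemeTable | None = None) -> NumberedChain | None:
    """Number a variable-domain sequence; returns None on clean failure."""
    if role not in ("L", "H"):
        raise ValueError("role must be 'L' or 'H'")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    table = table or load_scheme_table()
    query = _sanitize(seq)
    if not query:
        return None
    template = table.template[role]
    base = table.base[role]
    aligned = _align_to_template(query, template)
    if aligned is None:
        return None
    t_to_q, insertions = aligned

    # clean-failure test: at least half the conserved anchors must carry the
    # template residue
    matched = 0
    anchor_nums = table.anchors[role]
    for num in anchor_nums:
        ti = table.base_index[role][(num, "")]
        qi = t_to_q.get(ti)
        if qi is not None and query[qi] == template[ti]:
            matched += 1
    if matched < 0.5 * len(anchor_nums):
        return None

    # relocate insertion runs attached to a base position that has canonical
    # insertion columns (e.g. heavy 82) to after the last such column
    for ti in sorted(insertions):
        num = base[ti][0]
        last = max(i for i, (n, _) in enumerate(base) if n == num)
        if last != ti:
            insertions.setdefault(last, [])
            insertions[last].extend(insertions.pop(ti))

    anchors_for = table.insertion_anchors[scheme][role]
    residues: list = []
    taken: set = set()

    for region_name, start, end in table.regions[role]:
        idxs = [i for i, (n, _) in enumerate(base) if start <= n <= end]
        B = [base[i] for i in idxs]
        q_list: list = []
        for i in idxs:
            if i in t_to_q:
                q_list.append(t_to_q[i])
            q_list.extend(insertions.get(i, ()))
        if not q_list:
            continue
        anchor_num = anchors_for.get(region_name)
        labels: list
        if anchor_num is not None:
            a_idx = B.index((anchor_num, ""))
            n, m = len(q_list), len(B)
            if n >= m:
                extra = n - m
                if extra > 26:
                    return None
                ins = [(anchor_num, chr(ord("A") + k)) for k in range(extra)]
                labels = B[:a_idx + 1] + ins + B[a_idx + 1:]
            elif n <= a_idx + 1:
                labels = B[:n]
            else:
                labels = B[:a_idx + 1] + B[m - (n - a_idx - 1):]
        else:
            labels = []
            for i in idxs:
                if i in t_to_q:
                    labels.append(base[i])
                for _ in insertions.get(i, ()):
                    labels.append((base[i][0], _next_insertion_letter(
                        base[i][0], taken | set(labels) | set(B))))
        for (num, ins), qi in zip(labels, q_list):
            if (num, ins) in taken:
                return None  # label collision: refuse to mis-number
            taken.add((num, ins))
            residues.append(NumberedResidue(role, num, ins, query[qi], qi))

    if not residues:
        return None
    # all-or-nothing sanity: source indices must be strictly increasing
    if any(a.seq_index >= b.seq_index for a, b in zip(residues, residues[1:])):
        return None
    return NumberedChain(role=role, scheme=scheme, residues=residues)


_LABEL_RE = re.compile(r"^([LH])?(\d+)([A-Z]?)$")


def cdr_membership(label: str, role: str, scheme: str,
                   table: SchemeTable | None = None,
                   definition: str = "kabat") -> str:
    """CDR id (e.g. ``CDR-L1``) or ``framework`` for a numbered position.

    ``scheme`` names the numbering the label was produced under; the ranges
    applied are those of ``definition`` (Kabat by default) expressed in that
    label space.
    """
    table = table or load_scheme_table()
    m = _LABEL_RE.match(str(label).strip())
    if not m or (m.group(1) and m.group(1) != role):
        raise ValueError(f"invalid position label {label!r} for role {role}")
    num = int(m.group(2))
    if not 1 <= num <= table.max_num(role):
        raise ValueError(f"position {label!r} outside the {role} variable domain")
    for cdr_name, (start, end) in table.cdr_definitions[definition][role].items():
        if start <= num <= end:
            return cdr_name
    return "framework"


def _mapping_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.match_score = 2.0
    a.mismatch_score = -2.0
    a.open_gap_score = -4.0
    a.extend_gap_score = -0.5
    a.mode = "global"
    _free_end_gaps(a)
    return a


def renumber_structure(model: pdbio.StructureModel, chain_label: str,
                       numbered: NumberedChain, new_label: str) -> list:
    """Relabel a chain's Fv atoms with scheme numbering.

    The ATOM-derived sequence is aligned to the numbered sequence so that
    unmodelled residues (numbered from SEQRES but absent from the
    coordinates) and constant-domain residues (observed but not numbered) are
    both handled.  Atoms of constant-domain and leader residues are dropped.
    Raises :class:`NumberingFailure` if an observed Fv residue cannot be
    mapped — the entry must then be rejected, never mis-numbered.
    """
    residues = model.residues_of_chain(chain_label)
    if not residues:
        raise NumberingFailure(f"chain {chain_label!r} has no polymer residues")
    atom_seq = "".join(pdbio.three_to_one(r[3]) for r in residues)
    num_seq = numbered.sequence
    aln = _mapping_aligner().align(num_seq, atom_seq)[0]
    t_blocks, q_blocks = aln.aligned
    q_to_t: dict = {}
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for k in range(te - ts):
            q_to_t[qs + k] = ts + k
    if not q_to_t:
        raise NumberingFailure(f"chain {chain_label!r}: no overlap with numbered sequence")
    mapped = sorted(q_to_t)
    for qi in range(mapped[0], mapped[-1] + 1):
        if qi not in q_to_t:
            raise NumberingFailure(
                f"chain {chain_label!r}: residue {residues[qi][1]}{residues[qi][2]} "
                f"cannot be mapped onto the numbering")
    atoms_by_residue: dict = {}
    for a in model.chain_atoms(chain_label):
        atoms_by_residue.setdefault(a.residue_id, []).append(a)
    out = []
    for qi in mapped:
        nr = numbered.residues[q_to_t[qi]]
        if _sanitize(atom_seq[qi]) != nr.aa and atom_seq[qi] != "X" and nr.aa != "X":
            raise NumberingFailure(
                f"chain {chain_label!r}: residue mismatch at {nr.label} "
                f"({atom_seq[qi]} vs {nr.aa})")
        for a in atoms_by_residue[residues[qi]]:
            out.append(replace(a, chain_label=new_label, res_seq=nr.number,
                               i_code=nr.insertion))
    return out
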