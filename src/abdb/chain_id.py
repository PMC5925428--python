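"""Antibody chain-type identification.

Each polymer chain of an entry is aligned against frozen light- and
heavy-chain variable-domain consensus sequences (shipped as package data) and
scored as the percent identity of the best local alignment relative to the
consensus length.  The chain is provisionally typed by whichever consensus
scores higher, and provisional antibody chains are demoted to antigen when
some other chain scores strictly higher against the same consensus and their
own score falls below the threshold (80% by default).  Both the SEQRES- and
ATOM-derived sequences are scored and the better source kept, which copes
with unmodelled loops and with leader peptides present only in SEQRES.

Chains whose sequence contains *two* high-scoring variable-domain segments
(single-chain Fvs sharing one chain label) are flagged as hybrids and the
entry is rejected, as are entries with no variable domain at all (Fc-only).
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from . import pdbio

_BLOSUM_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize(seq: str) -> str:
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in seq.upper())


def _read_fasta_seq(package_file: str) -> str:
    text = resources.files("abdb.data").joinpath(package_file).read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


@dataclass(frozen=True)
class ConsensusProfile:
    """Scoring profile: consensus sequences plus alignment parameters."""
    light_consensus: str
    heavy_consensus: str
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self):
        if not self.light_consensus or not self.heavy_consensus:
            raise ValueError("consensus sequences must be non-empty")


@functools.lru_cache(maxsize=1)
def load_default_profile() -> ConsensusProfile:
    return ConsensusProfile(
        light_consensus=_read_fasta_seq("consensus_light.fasta"),
        heavy_consensus=_read_fasta_seq("consensus_heavy.fasta"),
    )


@dataclass
class ChainTypeCall:
    chain_label: str
    light_score: float
    heavy_score: float
    provisional: str  # light | heavy
    final: str        # light | heavy | antigen
    source: str       # seqres | atom
    hybrid: bool = False

    def __post_init__(self):
        if not (0 <= self.light_score <= 100 and 0 <= self.heavy_score <= 100):
            raise ValueError("scores must lie in [0, 100]")


@dataclass
class AntibodyForm:
    form: str  # complete | light_only | heavy_only | rejected
    reject_reason: str = "none"  # fc_only | scfv_hybrid | numbering_failure | none

    def __post_init__(self):
        if (self.reject_reason == "none") != (self.form != "rejected"):
            raise ValueError("reject_reason must be set iff form is 'rejected'")


def _aligner(profile: ConsensusProfile) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load(profile.substitution_matrix)
    a.open_gap_score = profile.gap_open
    a.extend_gap_score = profile.gap_extend
    a.mode = "local"
    return a


def _identity_vs_consensus(seq: str, consensus: str, profile: ConsensusProfile):
    """(percent identity over consensus length, query span of the best alignment)."""
    aligner = _aligner(profile)
    try:
        aln = aligner.align(consensus, seq)[0]
    except (IndexError, ValueError):
        return 0.0, (0, 0)
    identities = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        identities += sum(1 for tc, qc in zip(consensus[ts:te], seq[qs:qe]) if tc == qc)
    blocks = aln.aligned[1]
    span = (int(blocks[0][0]), int(blocks[-1][1])) if len(blocks) else (0, 0)
    return 100.0 * identities / len(consensus), span


def score_chain(seq: str, profile: ConsensusProfile) -> tuple[float, float]:
    """Light and heavy percent-identity scores for one sequence.

    Score = 100 x (identities in best local alignment) / (consensus length),
    so a chain equal to a consensus scores exactly 100 against it.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    s = _sanitize(seq)
    light, _ = _identity_vs_consensus(s, profile.light_consensus, profile)
    heavy, _ = _identity_vs_consensus(s, profile.heavy_consensus, profile)
    return light, heavy


def _detect_hybrid(seq: str, profile: ConsensusProfile, threshold: float) -> bool:
    """True when the chain holds two separate high-scoring variable domains."""
    s = _sanitize(seq)
    scores = {}
    for role, cons in (("light", profile.light_consensus), ("heavy", profile.heavy_consensus)):
        scores[role] = _identity_vs_consensus(s, cons, profile)
    best_role = max(scores, key=lambda r: scores[r][0])
    best_score, (qs, qe) = scores[best_role]
    if best_score < threshold or qe <= qs:
        return False
    masked = s[:qs] + "X" * (qe - qs) + s[qe:]
    rest_light, _ = _identity_vs_consensus(masked, profile.light_consensus, profile)
    rest_heavy, _ = _identity_vs_consensus(masked, profile.heavy_consensus, profile)
    return max(rest_light, rest_heavy) >= threshold


def assign_chain_types(model: pdbio.StructureModel,
                       profile: ConsensusProfile | None = None,
                       threshold: float = 80.0) -> list[ChainTypeCall]:
    """Type every polymer chain of an entry as light, heavy or antigen."""
    profile = profile or load_default_profile()
    calls = []
    for ch in model.polymer_chains():
        if model.is_nucleic(ch):
            calls.append(ChainTypeCall(ch, 0.0, 0.0, "light", "antigen", "atom"))
            continue
        candidates = []  # (max score, source, light, heavy, seq)
        try:
            atom_seq = pdbio.sequence_from_atoms(model, ch)
        except KeyError:
            atom_seq = ""
        if atom_seq:
            l, h = score_chain(atom_seq, profile)
            candidates.append((max(l, h), "atom", l, h, atom_seq))
        seqres_seq = model.seqres.get(ch, "")
        if seqres_seq:
            l, h = score_chain(seqres_seq, profile)
            candidates.append((max(l, h), "seqres", l, h, seqres_seq))
        if not candidates:
            calls.append(ChainTypeCall(ch, 0.0, 0.0, "light", "antigen", "atom"))
            continue
        _best, source, light, heavy, seq = max(candidates, key=lambda c: c[0])
        provisional = "light" if light >= heavy else "heavy"
        hybrid = (max(light, heavy) >= threshold
                  and _detect_hybrid(seq, profile, threshold))
        calls.append(ChainTypeCall(ch, light, heavy, provisional, provisional,
                                   source, hybrid=hybrid))
    # demotion pass: a provisional light (heavy) chain becomes antigen when another
    # chain scores strictly higher against the light (heavy) consensus and its own
    # score is below the threshold
    if calls:
        max_light = max(c.light_score for c in calls)
        max_heavy = max(c.heavy_score for c in calls)
        for c in calls:
            if c.final == "light" and c.light_score < max_light and c.light_score < threshold:
                c.final = "antigen"
            elif c.final == "heavy" and c.heavy_score < max_heavy and c.heavy_score < threshold:
                c.final = "antigen"
    return calls


def classify_form(calls: list[ChainTypeCall], threshold: float = 80.0) -> AntibodyForm:
    """Decide the entry's antibody form from its chain-type calls."""
    if not calls:
        raise ValueError("no chain calls")
    if any(c.hybrid for c in calls):
        return AntibodyForm("rejected", "scfv_hybrid")
    lights = [c for c in calls if c.final == "light"]
    heavies = [c for c in calls if c.final == "heavy"]
    best = max((max(c.light_score, c.heavy_score) for c in lights + heavies), default=0.0)
    if best < threshold:
        return AntibodyForm("rejected", "fc_only")
    if lights and heavies:
        return AntibodyForm("complete")
    if lights:
        return AntibodyForm("light_only")
    return AntibodyForm("heavy_only")
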