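"""Tolerant parsing and canonicalization of protein-level HGVS strings.

Laboratories describe the same protein change in many dialects: optional
``p.`` prefix, optional parentheses, one- or three-letter amino-acid codes,
``*``/``Ter`` for stop codons, and occasionally a hyphen instead of the
prescribed underscore in residue ranges. This module collapses all of them
onto a single canonical rendering (three-letter codes, parentheses, ``*``
for stop, ``_`` range separator) so that reports from different
laboratories land on common variant keys.

Only protein syntax is handled. DNA-level (c.) normalization and 3'-rule
shifting against a reference sequence are out of scope: no reference genome
is bundled, and the assessment itself is protein-level.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional

from .schemas import OrderedVariant, ReportedVariant

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class HgvsParseError(ValueError):
    """Raised when a protein HGVS string cannot be interpreted."""


class ChangeKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"


@dataclass(frozen=True)
class ProteinChange:
    """A parsed protein-level change in three-letter vocabulary."""

    kind: ChangeKind
    ref_residues: tuple[tuple[str, int], ...]
    alt_residues: tuple[str, ...] = ()
    fs_new_residue: Optional[str] = None
    fs_term_offset: Optional[int] = None

    def __post_init__(self) -> None:
        positions = [p for _, p in self.ref_residues]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("reference residue positions must strictly increase")
        if self.kind in (ChangeKind.SUBSTITUTION, ChangeKind.NONSENSE):
            if len(self.ref_residues) != 1 or len(self.alt_residues) != 1:
                raise ValueError("substitution needs exactly one ref and one alt")
        if self.kind is ChangeKind.FRAMESHIFT and self.fs_term_offset is not None:
            if self.fs_term_offset < 1:
                raise ValueError("fs*N offset must be >= 1")


# A residue token: three-letter code, 'Ter', '*', or a one-letter code.
_RES = r"(?:Ter|[A-Z][a-z]{2}|\*|[A-Z])"
_FS_RE = re.compile(
    rf"^({_RES})(\d+)({_RES})?fs(?:(?:\*|Ter)(\d+))?$"
)
_RANGE_RE = re.compile(
    rf"^({_RES})(\d+)[_-]({_RES})(\d+)(delins|del|dup|ins)((?:{_RES})*)$"
)
_SINGLE_OP_RE = re.compile(rf"^({_RES})(\d+)(delins|del|dup)((?:{_RES})*)$")
_SUBST_RE = re.compile(rf"^({_RES})(\d+)({_RES})$")
_RES_SPLIT_THREE = re.compile(r"Ter|[A-Z][a-z]{2}|\*")


def _normalize_residue(token: str) -> str:
    """Map a residue token of either code length to the three-letter form."""
    if token == "*":
        return "Ter"
    if token in THREE_TO_ONE:
        return token
    if token in ONE_TO_THREE:
        return ONE_TO_THREE[token]
    raise HgvsParseError(f"unknown amino-acid code {token!r}")


def _split_residues(text: str) -> tuple[str, ...]:
    """Split a residue run ('IlePro' or 'IP') into three-letter codes.

    Three-letter reading is attempted first; a run that does not tile into
    valid three-letter codes is re-read as one-letter codes. A run valid
    under neither reading is a parse failure.
    """
    if not text:
        return ()
    tokens = _RES_SPLIT_THREE.findall(text)
    if "".join(tokens) == text and all(t in THREE_TO_ONE or t == "*" for t in tokens):
        return tuple("Ter" if t == "*" else t for t in tokens)
    if all(ch in ONE_TO_THREE for ch in text):
        return tuple(ONE_TO_THREE[ch] for ch in text)
    raise HgvsParseError(f"ambiguous or invalid residue run {text!r}")


def parse_protein_hgvs(text: str) -> ProteinChange:
    """Parse one protein-level HGVS string, tolerating common dialects.

    Raises :class:`HgvsParseError` on anything unparseable; callers fall
    back to genomic-coordinate matching in that case.
    """
    if not text or not text.strip():
        raise HgvsParseError("empty protein HGVS string")
    s = text.strip()
    s = re.sub(r"^p\.?", "", s)  # optional 'p.' or bare 'p'
    s = s.strip()
    if s.startswith("(") and s.endswith(")"):
        s = s[1:-1]
    if "(" in s or ")" in s or not s:
        raise HgvsParseError(f"malformed protein HGVS {text!r}")

    m = _FS_RE.match(s)
    if m:
        ref, pos, new, off = m.groups()
        return ProteinChange(
            kind=ChangeKind.FRAMESHIFT,
            ref_residues=((_normalize_residue(ref), int(pos)),),
            fs_new_residue=_normalize_residue(new) if new else None,
            fs_term_offset=int(off) if off else None,
        )

    m = _RANGE_RE.match(s)
    if m:
        a1, p1, a2, p2, op, alt = m.groups()
        start, end = int(p1), int(p2)
        if start >= end:
            raise HgvsParseError(f"range positions not increasing in {text!r}")
        refs = ((_normalize_residue(a1), start), (_normalize_residue(a2), end))
        alts = _split_residues(alt)
        if op in ("del", "dup") and alts:
            raise HgvsParseError(f"unexpected residues after {op} in {text!r}")
        if op in ("ins", "delins") and not alts:
            raise HgvsParseError(f"{op} without inserted residues in {text!r}")
        kind = {
            "del": ChangeKind.DELETION,
            "dup": ChangeKind.DUPLICATION,
            "ins": ChangeKind.INSERTION,
            "delins": ChangeKind.DELINS,
        }[op]
        return ProteinChange(kind=kind, ref_residues=refs, alt_residues=alts)

    m = _SINGLE_OP_RE.match(s)
    if m:
        aa, pos, op, alt = m.groups()
        refs = ((_normalize_residue(aa), int(pos)),)
        alts = _split_residues(alt)
        if op in ("del", "dup"):
            if alts:
                raise HgvsParseError(f"unexpected residues after {op} in {text!r}")
            kind = ChangeKind.DELETION if op == "del" else ChangeKind.DUPLICATION
            return ProteinChange(kind=kind, ref_residues=refs)
        if not alts:
            raise HgvsParseError(f"delins without inserted residues in {text!r}")
        return ProteinChange(kind=ChangeKind.DELINS, ref_residues=refs, alt_residues=alts)

    m = _SUBST_RE.match(s)
    if m:
        ref, pos, alt = m.groups()
        ref3 = _normalize_residue(ref)
        alt3 = _normalize_residue(alt)
        if ref3 == "Ter":
            raise HgvsParseError(f"stop codon as substitution reference in {text!r}")
        kind = ChangeKind.NONSENSE if alt3 == "Ter" else ChangeKind.SUBSTITUTION
        return ProteinChange(
            kind=kind, ref_residues=((ref3, int(pos)),), alt_residues=(alt3,)
        )

    raise HgvsParseError(f"unparseable protein HGVS {text!r}")


def _render_residue(aa3: str) -> str:
    return "*" if aa3 == "Ter" else aa3


def canonicalize(change: ProteinChange) -> str:
    """Render the deterministic canonical ``p.(...)`` string.

    A single-residue delins with a single inserted residue is the same
    molecular event as a substitution and is rewritten as one (so
    ``p.Val600delinsArg`` and ``p.(Val600Arg)`` collapse).
    """
    refs = change.ref_residues
    kind = change.kind
    if (
        kind is ChangeKind.DELINS
        and len(refs) == 1
        and len(change.alt_residues) == 1
    ):
        alt = change.alt_residues[0]
        kind = ChangeKind.NONSENSE if alt == "Ter" else ChangeKind.SUBSTITUTION

    if kind in (ChangeKind.SUBSTITUTION, ChangeKind.NONSENSE):
        (aa, pos), = refs
        return f"p.({aa}{pos}{_render_residue(change.alt_residues[0])})"
    if kind is ChangeKind.FRAMESHIFT:
        (aa, pos), = refs
        new = change.fs_new_residue or ""
        tail = f"fs*{change.fs_term_offset}" if change.fs_term_offset else "fs"
        return f"p.({aa}{pos}{new}{tail})"

    if len(refs) == 1:
        span = f"{refs[0][0]}{refs[0][1]}"
    else:
        span = f"{refs[0][0]}{refs[0][1]}_{refs[-1][0]}{refs[-1][1]}"
    if kind is ChangeKind.DELETION:
        return f"p.({span}del)"
    if kind is ChangeKind.DUPLICATION:
        return f"p.({span}dup)"
    alt_run = "".join(change.alt_residues)
    op = "ins" if kind is ChangeKind.INSERTION else "delins"
    return f"p.({span}{op}{alt_run})"


@dataclass(frozen=True)
class VariantKey:
    """Identity used to match reported variants to truth variants.

    Protein-level identity is preferred; when the protein string cannot be
    parsed the key falls back to the genomic coordinate. The two levels are
    never mixed: a protein key and a genomic fallback key never compare
    equal, mirroring the protein-level focus of the assessment.
    """

    gene: str
    canonical_p: Optional[str] = None
    fallback: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.upper())
        if self.canonical_p is None and self.fallback is None:
            raise ValueError("key needs a canonical protein string or a genomic fallback")

    @property
    def label(self) -> str:
        if self.canonical_p:
            return f"{self.gene} {self.canonical_p}"
        chrom, pos = self.fallback  # type: ignore[misc]
        return f"{self.gene} {chrom}:{pos}"


def key_for(gene: str, p_hgvs: str, chrom: Optional[str] = None,
            pos: Optional[int] = None) -> VariantKey:
    """Build the matching key, falling back to coordinates on parse failure."""
    try:
        canonical = canonicalize(parse_protein_hgvs(p_hgvs))
        return VariantKey(gene=gene, canonical_p=canonical)
    except HgvsParseError:
        if chrom is not None and pos is not None:
            return VariantKey(gene=gene, fallback=(str(chrom), int(pos)))
        raise


def key_for_report(rv: ReportedVariant) -> VariantKey:
    return key_for(rv.gene, rv.p_hgvs_raw, rv.chrom, rv.pos)


def key_for_ordered(ov: OrderedVariant) -> VariantKey:
    return key_for(ov.gene, ov.p_hgvs, ov.chrom, ov.pos)


def variants_equivalent(reported: ReportedVariant, ordered: OrderedVariant) -> bool:
    """True iff a reported variant designates an ordered truth variant.

    Gene symbols must match case-insensitively. Frameshifts with the same
    start but different (or one missing) ``fs*N`` offsets are conservatively
    non-equivalent; the canonical string carries the offset, so plain key
    equality already enforces this.
    """
    if reported.gene.upper() != ordered.gene.upper():
        return False
    try:
        a = canonicalize(parse_protein_hgvs(reported.p_hgvs_raw))
        b = canonicalize(parse_protein_hgvs(ordered.p_hgvs))
        return a == b
    except HgvsParseError:
        if reported.chrom is None or reported.pos is None:
            return False
        return str(reported.chrom) == str(ordered.chrom) and int(reported.pos) == ordered.pos
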