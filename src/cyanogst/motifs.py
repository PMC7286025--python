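"""Degenerate-motif engine: class definitions, motif scanning, class assignment.

The 12 cyanobacterial GST classes are each marked by a 5-residue degenerate
motif (a generalisation of the SNAIL/TRAIL glutathione-binding motif) near the
N-terminal G-site.  Classes Chi and cyGSTX1 share the motif SGAIL and are told
apart only by N-/C-terminal signature motifs; a global permissive architecture
S[GLNTARS][ADE]I[LAI] acts as a "GST-like" pre-filter and is never used for
class assignment (four class motifs fall outside it).
"""

from __future__ import annotations

import configparser
import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from cyanogst.seqio import ORDERS, ProteinRecord, ValidationError

AA_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: one-letter ambiguity codes expanded during motif parsing
MOTIF_AMBIGUITY = {"B": "ND"}
#: catalytic residue positions (1-based) accepted for each type
TYPE_POSITIONS = {"Y": (5, 7), "S": (8, 66), "C": (12, 26, 74)}
#: permissive GST-like pre-filter; not a class assigner
GLOBAL_ARCHITECTURE_SPEC = "S[GLNTARS][ADE]I[LAI]"


class MotifParseError(ValueError):
    """Raised for malformed degenerate-motif specifications."""


@dataclass(frozen=True)
class DegenerateMotif:
    """Ordered residue-alternative sets, e.g. SD(DRV)I(IL)."""

    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise MotifParseError("motif must have at least one position")
        for alts in self.positions:
            if not alts:
                raise MotifParseError("empty alternative group")
            bad = set(alts) - AA_CODES
            if bad:
                raise MotifParseError(f"invalid residue(s) {sorted(bad)} in motif")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def cardinality(self) -> int:
        """Number of concrete expansions (product of group sizes)."""
        n = 1
        for alts in self.positions:
            n *= len(alts)
        return n

    def expansions(self) -> list[str]:
        """All concrete strings matching the motif, lexicographically sorted."""
        return sorted(
            "".join(combo)
            for combo in itertools.product(*(sorted(a) for a in self.positions))
        )

    def matches_at(self, residues: str, offset: int) -> bool:
        if offset < 0 or offset + len(self) > len(residues):
            return False
        return all(
            residues[offset + k] in alts for k, alts in enumerate(self.positions)
        )

    def contains(self, other: "DegenerateMotif") -> bool:
        """True iff every expansion of ``other`` is an expansion of self."""
        if len(other) != len(self):
            return False
        return all(o <= s for o, s in zip(other.positions, self.positions))

    def to_spec(self) -> str:
        out = []
        for alts in self.positions:
            letters = "".join(sorted(alts))
            out.append(letters if len(letters) == 1 else f"[{letters}]")
        return "".join(out)


def parse_motif(spec: str) -> DegenerateMotif:
    """Parse bracket notation — ``SNA(IV)L`` or ``S[GLNTARS][ADE]I[LAI]``.

    ``B`` is interpreted as Asx = [ND].  Raises :class:`MotifParseError` with
    the character offset for unbalanced brackets, empty groups or invalid
    residues.
    """
    spec = spec.strip()
    positions: list[frozenset[str]] = []
    i = 0
    closers = {"(": ")", "[": "]"}
    while i < len(spec):
        ch = spec[i]
        if ch in closers:
            end = spec.find(closers[ch], i + 1)
            if end < 0:
                raise MotifParseError(f"unbalanced {ch!r} at offset {i} in {spec!r}")
            group = spec[i + 1 : end]
            if not group:
                raise MotifParseError(f"empty group at offset {i} in {spec!r}")
            letters: set[str] = set()
            for c in group:
                letters.update(MOTIF_AMBIGUITY.get(c, c))
            positions.append(frozenset(letters))
            i = end + 1
        elif ch in (")", "]"):
            raise MotifParseError(f"unbalanced {ch!r} at offset {i} in {spec!r}")
        elif ch.isspace():
            i += 1
        else:
            positions.append(frozenset(MOTIF_AMBIGUITY.get(ch, ch)))
            i += 1
    try:
        return DegenerateMotif(tuple(positions))
    except MotifParseError as exc:
        raise MotifParseError(f"{exc} (in {spec!r})") from None


GLOBAL_ARCHITECTURE = parse_motif(GLOBAL_ARCHITECTURE_SPEC)


def scan(seq: ProteinRecord | str, motif: DegenerateMotif) -> list[int]:
    """All 0-based offsets where the motif matches (set-membership semantics)."""
    residues = seq.residues if isinstance(seq, ProteinRecord) else seq
    upper = len(residues) - len(motif)
    return [i for i in range(upper + 1) if motif.matches_at(residues, i)]


def is_gst_like(seq: ProteinRecord | str) -> bool:
    """Permissive pre-filter: does the global architecture match anywhere?"""
    return bool(scan(seq, GLOBAL_ARCHITECTURE))


@dataclass(frozen=True)
class ClassDefinition:
    """One GST class: motif architecture, optional signatures, catalytic rule."""

    name: str
    architecture: DegenerateMotif
    catalytic_type: str
    catalytic_positions: tuple[int, ...]
    per_order_variants: dict[str, DegenerateMotif] = field(default_factory=dict)
    signature_n: DegenerateMotif | None = None
    signature_c: DegenerateMotif | None = None

    def __post_init__(self) -> None:
        if self.catalytic_type not in "YSC":
            raise ValidationError(
                f"{self.name}: catalytic type must be Y, S or C"
            )
        for order in self.per_order_variants:
            if order not in ORDERS:
                raise ValidationError(f"{self.name}: unknown order {order!r}")

    @property
    def orders(self) -> tuple[str, ...]:
        """Orders in which the class occurs (those with a motif variant)."""
        return tuple(o for o in ORDERS if o in self.per_order_variants)

    @property
    def catalytic_residue(self) -> str:
        return self.catalytic_type


def _natural_key(name: str) -> tuple:
    return tuple(
        int(tok) if tok.isdigit() else tok
        for tok in re.split(r"(\d+)", name)
    )


def class_rank(name: str, classes: list[ClassDefinition]) -> tuple:
    """Deterministic numeric-aware ordering: Chi < cyGSTX1 < ... < cyGSTX11."""
    for k, cdef in enumerate(classes):
        if cdef.name == name:
            return (0, k)
    return (1, _natural_key(name))


def load_class_definitions(path: str | Path | None = None) -> list[ClassDefinition]:
    """Load class definitions from the shipped (or a user-supplied) config file."""
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keep case
    if path is None:
        text = (
            resources.files("cyanogst.data").joinpath("gst_classes.cfg").read_text()
        )
    else:
        text = Path(path).read_text()
    parser.read_string(text)
    classes = []
    for name in parser.sections():
        sec = parser[name]
        variants = {}
        for key, value in sec.items():
            if key.startswith("variant."):
                variants[key.split(".", 1)[1]] = parse_motif(value)
        classes.append(
            ClassDefinition(
                name=name,
                architecture=parse_motif(sec["architecture"]),
                catalytic_type=sec["catalytic_type"].strip(),
                catalytic_positions=tuple(
                    int(tok) for tok in sec["catalytic_positions"].split()
                ),
                per_order_variants=variants,
                signature_n=parse_motif(sec["signature_n"])
                if "signature_n" in sec
                else None,
                signature_c=parse_motif(sec["signature_c"])
                if "signature_c" in sec
                else None,
            )
        )
    if not classes:
        raise ValidationError("class definition file contains no classes")
    return classes


def distinctive_expansions(
    cdef: ClassDefinition, classes: list[ClassDefinition]
) -> list[str]:
    """Expansions of ``cdef``'s architecture unique to it among ``classes``.

    Signature-bearing classes that share an identical architecture (Chi and
    cyGSTX1, both SGAIL) are not subtracted from each other: their motif is
    intentionally shared and resolution is by signature.
    """
    base = set(cdef.architecture.expansions())
    keep = set(base)
    for other in classes:
        if other.name == cdef.name:
            continue
        theirs = set(other.architecture.expansions())
        if (
            cdef.signature_n is not None
            and other.signature_n is not None
            and theirs == base
        ):
            continue
        keep -= theirs
    return sorted(keep)


@dataclass
class ClassAssignment:
    """Classifier verdict for one sequence."""

    sequence_id: str
    class_name: str  # class name or "unclassified"
    matched_motif: str = ""
    match_position: int = -1
    candidates: tuple[str, ...] = ()
    ambiguous: bool = False
    signature_evidence: dict[str, int] = field(default_factory=dict)
    catalytic_type_called: str = "none"
    catalytic_concordant: bool = False

    @property
    def classified(self) -> bool:
        return self.class_name != "unclassified"


def _catalytic_call(residues: str, cdef: ClassDefinition | None):
    """Type the catalytic residue.

    The assigned class's own residue/positions are checked first; if absent,
    the generic Y/S/C position rules are tried in that order.  Returns
    (type called or "none", concordant with the class definition).
    """
    if cdef is not None:
        res = cdef.catalytic_residue
        if any(
            p <= len(residues) and residues[p - 1] == res
            for p in cdef.catalytic_positions
        ):
            return cdef.catalytic_type, True
    for ctype in "YSC":
        if cdef is not None and ctype == cdef.catalytic_type:
            continue  # already checked with the class's own positions
        if any(
            p <= len(residues) and residues[p - 1] == ctype
            for p in TYPE_POSITIONS[ctype]
        ):
            return ctype, False
    return "none", False


def classify(
    seq: ProteinRecord,
    classes: list[ClassDefinition],
    policy: str = "rank",
) -> ClassAssignment:
    """Assign a GST class by scanning every class architecture.

    Candidates are all classes whose architecture matches anywhere.  When both
    signature-bearing SGAIL classes are candidates the signature motifs decide;
    any remaining multi-candidate tie is resolved by the deterministic
    numeric-aware class ordering (policy ``"rank"``, the default) with the
    ``ambiguous`` flag set — never silently.  With policy ``"strict"`` ties are
    left unresolved (``class_name`` = "unclassified", flag set).
    """
    if policy not in ("rank", "strict"):
        raise ValidationError(f"unknown tie policy {policy!r}")
    residues = seq.residues
    hits: dict[str, int] = {}
    for cdef in classes:
        pos = scan(residues, cdef.architecture)
        if pos:
            hits[cdef.name] = pos[0]
    candidates = tuple(
        sorted(hits, key=lambda n: class_rank(n, classes))
    )
    by_name = {c.name: c for c in classes}

    evidence: dict[str, int] = {}
    pool = list(candidates)
    ambiguous = False

    sig_pool = [
        n
        for n in pool
        if by_name[n].signature_n is not None or by_name[n].signature_c is not None
    ]
    if len(sig_pool) >= 2:
        for name in sig_pool:
            cdef = by_name[name]
            ev = 0
            if cdef.signature_n is not None and scan(residues, cdef.signature_n):
                ev += 1
            if cdef.signature_c is not None and scan(residues, cdef.signature_c):
                ev += 1
            evidence[name] = ev
        supported = [n for n in sig_pool if evidence[n] > 0]
        if len(supported) == 1:
            pool = [n for n in pool if n not in sig_pool or n == supported[0]]
        else:
            # neither or both signatures present: keep all, flag ambiguity
            ambiguous = True

    if not pool:
        name = "unclassified"
    elif len(pool) == 1 and not ambiguous:
        name = pool[0]
    else:
        ambiguous = True
        name = "unclassified" if policy == "strict" else pool[0]

    if name != "unclassified":
        cdef = by_name[name]
        pos = hits[name]
        motif_len = len(cdef.architecture)
        matched = residues[pos : pos + motif_len]
        called, concordant = _catalytic_call(residues, cdef)
    else:
        matched, pos = "", -1
        called, concordant = _catalytic_call(residues, None)

    return ClassAssignment(
        sequence_id=seq.id,
        class_name=name,
        matched_motif=matched,
        match_position=pos,
        candidates=candidates,
        ambiguous=ambiguous,
        signature_evidence=evidence,
        catalytic_type_called=called,
        catalytic_concordant=concordant,
    )


def classify_all(
    seqs, classes: list[ClassDefinition], policy: str = "rank"
) -> list[ClassAssignment]:
    return [classify(rec, classes, policy) for rec in seqs]


@dataclass
class IncidenceMatrix:
    """Order × class presence grid with derived per-order class counts."""

    table: pd.DataFrame  # bool, rows = orders, columns = classes

    @property
    def counts(self) -> pd.Series:
        return self.table.sum(axis=1).astype(int)

    def to_tsv(self, path) -> None:
        out = self.table.astype(int)
        out.index.name = "order"
        out.to_csv(path, sep="\t")


def build_incidence(
    assignments: list[ClassAssignment],
    orders: dict[str, str],
    class_names: list[str] | None = None,
) -> IncidenceMatrix:
    """Presence/absence of each class in each order, from classifier output.

    Unclassified sequences are ignored; an unknown order label raises.
    """
    if class_names is None:
        class_names = sorted(
            {a.class_name for a in assignments if a.classified},
            key=_natural_key,
        )
    table = pd.DataFrame(False, index=list(ORDERS), columns=class_names)
    for a in assignments:
        if not a.classified:
            continue
        order = orders.get(a.sequence_id)
        if order is None or order not in ORDERS:
            raise ValidationError(
                f"{a.sequence_id}: missing or unknown order label {order!r}"
            )
        if a.class_name in table.columns:
            table.loc[order, a.class_name] = True
    return IncidenceMatrix(table)


def reference_incidence() -> IncidenceMatrix:
    """The published order × class survey grid shipped with the package."""
    text = (
        resources.files("cyanogst.data")
        .joinpath("order_class_incidence.tsv")
        .read_text()
    )
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", index_col=0).astype(bool)
    return IncidenceMatrix(df)
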