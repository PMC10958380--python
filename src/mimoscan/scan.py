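"""Proteome scanning for recognition-motif matches.

Scans protein FASTA files with a :class:`~mimoscan.motif.RecognitionMotif`
or a list of degenerate octamer :class:`~mimoscan.motif.SearchPattern`
strings, completes matched octamers into nonamers by supplementing P1 from
the natural flanking sequence, applies curation rules (by default: Arg at
P6 forbids a hit, since it prevents TCR activation despite an intact
motif), and ranks hits with a log-odds score against a background
composition.

Coordinates are 0-based half-open internally; TSV output uses 1-based
inclusive starts.
"""

from __future__ import annotations

import copy
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import (
    AA_INDEX,
    AA_SET,
    AMINO_ACIDS,
    MotifError,
    Peptide,
    PositionFrequencyModel,
    RecognitionMotif,
    SearchPattern,
)

logger = logging.getLogger(__name__)

UNIFORM_BACKGROUND = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}

OCTAMER_LEN = 8


class ScanError(ValueError):
    """Raised for malformed proteome input."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ScanError("protein record id must be non-empty")
        if not self.sequence:
            raise ScanError(f"protein {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class MotifHit:
    """A matched octamer window within a protein.

    ``start`` is the 0-based offset of the octamer.  ``nonamer`` and
    ``p1_residue`` are filled by :func:`complete_nonamer`; hits at offset 0
    have no upstream residue and stay octamer-only with flag ``no_P1``.
    """

    protein_id: str
    start: int
    octamer: Peptide
    nonamer: Peptide | None = None
    p1_residue: str | None = None
    curation_flags: set[str] = field(default_factory=set)
    score: float | None = None
    annotations: dict = field(default_factory=dict)

    def residue_at(self, position: int) -> str | None:
        """Residue at nonamer position, from the nonamer if completed."""
        if self.nonamer is not None:
            return self.nonamer.residue_at(position)
        return self.octamer.residue_at(position)

    def sort_key(self) -> tuple[str, int]:
        return (self.protein_id, self.start)


@dataclass(frozen=True)
class CurationRuleSet:
    """Forbidden residues per nonamer position, plus optional P3/P4 weights.

    The default forbids Arg at P6 (present in motif-positive but
    non-stimulatory ligands).  ``preference_weights`` may hold
    position -> residue -> weight maps for ranking; no default is shipped.
    """

    forbidden: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: {6: frozenset("R")}
    )
    preference_weights: Mapping[int, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        forb = {int(p): frozenset(v) for p, v in self.forbidden.items()}
        if set(forb) - set(range(1, 10)):
            raise ScanError("curation rule positions must lie in P1..P9")
        object.__setattr__(self, "forbidden", forb)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) FASTA file into ProteinRecords.

    Sequences are uppercased; '*' stop symbols are stripped with a warning.
    A file whose first non-blank line is not a header, or a header with an
    empty id, raises :class:`ScanError` naming the line.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ScanError(
                    f"{path.name}:{lineno}: expected FASTA header, got {stripped[:30]!r}"
                )
            if stripped == ">":
                raise ScanError(f"{path.name}:{lineno}: FASTA header has no id")
            break
        else:
            return []
        handle.seek(0)
        n_headers = 0
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                n_headers += 1
                if not line[1:].strip():
                    raise ScanError(
                        f"{path.name}:{lineno}: FASTA header has no id"
                    )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning(
                "protein %s: stripping %d stop symbol(s) '*'",
                rec.id, seq.count("*"),
            )
            seq = seq.replace("*", "")
        records.append(
            ProteinRecord(id=rec.id, description=rec.description, sequence=seq)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write ProteinRecords as wrapped FASTA (60 columns)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=r.description[len(r.id):].strip()
                  if r.description.startswith(r.id) else r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _motif_octamer_regex(motif: RecognitionMotif) -> re.Pattern:
    parts = []
    for pos in range(2, 10):
        admitted = sorted(motif.allowed_residues(pos))
        if not admitted:
            raise MotifError(f"P{pos}: no residue admitted")
        if len(admitted) == 1:
            parts.append(admitted[0])
        else:
            parts.append(f"[{''.join(admitted)}]")
    return re.compile(f"(?=({''.join(parts)}))")


def _pattern_regex(pattern: SearchPattern) -> re.Pattern:
    return re.compile(f"(?=({pattern.to_regex()}))")


def _ambiguous_window_count(sequence: str) -> int:
    """Number of octamer windows containing a non-standard residue."""
    n = len(sequence)
    n_windows = max(0, n - OCTAMER_LEN + 1)
    if n_windows == 0:
        return 0
    bad_positions = [i for i, c in enumerate(sequence) if c not in AA_SET]
    if not bad_positions:
        return 0
    covered: set[int] = set()
    for p in bad_positions:
        lo = max(0, p - OCTAMER_LEN + 1)
        hi = min(p, n_windows - 1)
        covered.update(range(lo, hi + 1))
    return len(covered)


def scan_proteome(
    proteins: Sequence[ProteinRecord],
    motif_or_patterns: RecognitionMotif | Sequence[SearchPattern],
) -> list[MotifHit]:
    """Scan every octamer window of every protein for motif matches.

    All overlapping hits are reported; windows containing non-standard
    residues (X, B, Z, J, U, O) are skipped and counted in the logged
    summary.  Scanning with a pattern list reports the deduplicated union
    of per-pattern hits.  Output order is deterministic: protein order,
    then offset.
    """
    if isinstance(motif_or_patterns, RecognitionMotif):
        regexes = [_motif_octamer_regex(motif_or_patterns)]
    else:
        regexes = [_pattern_regex(p) for p in motif_or_patterns]
    hits: list[MotifHit] = []
    n_windows = 0
    n_skipped = 0
    for protein in proteins:
        seq = protein.sequence
        n_windows += max(0, len(seq) - OCTAMER_LEN + 1)
        n_skipped += _ambiguous_window_count(seq)
        starts: set[int] = set()
        for rx in regexes:
            for m in rx.finditer(seq):
                starts.add(m.start())
        for start in sorted(starts):
            octamer = Peptide(seq[start:start + OCTAMER_LEN])
            hits.append(
                MotifHit(protein_id=protein.id, start=start, octamer=octamer)
            )
    logger.info(
        "scanned %d proteins, %d windows (%d skipped for ambiguity codes): %d hits",
        len(proteins), n_windows, n_skipped, len(hits),
    )
    return hits


def complete_nonamer(hit: MotifHit, protein: ProteinRecord) -> MotifHit:
    """Supplement P1 from the natural protein sequence upstream of the octamer.

    A hit at offset 0 has no upstream residue: it keeps ``nonamer`` absent
    and gains the flag ``no_P1`` (octamers lacking P1 can still stimulate).
    """
    if hit.protein_id != protein.id:
        raise ScanError(
            f"hit refers to protein {hit.protein_id!r}, got {protein.id!r}"
        )
    if protein.sequence[hit.start:hit.start + OCTAMER_LEN] != hit.octamer.sequence:
        raise ScanError(
            f"hit octamer does not match protein {protein.id!r} at offset {hit.start}"
        )
    out = replace(hit, curation_flags=set(hit.curation_flags),
                  annotations=dict(hit.annotations))
    if hit.start == 0:
        out.curation_flags.add("no_P1")
        return out
    p1 = protein.sequence[hit.start - 1]
    if p1 not in AA_SET:
        out.curation_flags.add("no_P1")
        out.annotations["p1_ambiguous"] = p1
        return out
    out.p1_residue = p1
    out.nonamer = Peptide(p1 + hit.octamer.sequence)
    return out


def curate_hits(
    hits: Iterable[MotifHit],
    rules: CurationRuleSet | None = None,
) -> tuple[list[MotifHit], list[MotifHit]]:
    """Partition hits into (kept, removed) under forbidden-residue rules.

    A hit is removed iff some forbidden rule fires; the reason (e.g.
    "P6:R forbidden") is recorded in its ``curation_flags``.  A rule on a
    position an octamer-only hit cannot express (P1) flags the hit
    ``unevaluable`` and keeps it.  Coordinates are never altered;
    kept + removed partition the input.
    """
    if rules is None:
        rules = CurationRuleSet()
    kept: list[MotifHit] = []
    removed: list[MotifHit] = []
    for hit in hits:
        reasons: list[str] = []
        unevaluable = False
        for pos, banned in sorted(rules.forbidden.items()):
            res = hit.residue_at(pos)
            if res is None:
                unevaluable = True
                continue
            if res in banned:
                reasons.append(f"P{pos}:{res} forbidden")
        out = replace(hit, curation_flags=set(hit.curation_flags),
                      annotations=dict(hit.annotations))
        if reasons:
            out.curation_flags.update(reasons)
            removed.append(out)
        else:
            if unevaluable:
                out.curation_flags.add("unevaluable")
                logger.warning(
                    "hit %s@%d: curation rule position not covered by octamer-only "
                    "hit; kept as unevaluable", hit.protein_id, hit.start,
                )
            kept.append(out)
    return kept, removed


def rank_hits(
    hits: Sequence[MotifHit],
    model: PositionFrequencyModel,
    background: Mapping[str, float] | None = None,
) -> list[MotifHit]:
    """Score hits by log-odds against a background and sort them.

    score = sum over covered nonamer positions of
    log2(model frequency / background frequency).  A residue never seen by
    a zero-pseudocount model scores -inf and sorts last.  Ties (and -inf
    scores) break deterministically by (protein_id, offset).
    """
    if background is None:
        background = UNIFORM_BACKGROUND
    zero = [aa for aa in AMINO_ACIDS if background.get(aa, 0.0) <= 0.0]
    if zero:
        raise ScanError(
            f"background frequency is zero for {zero}; supply a background "
            "pseudocount or a complete composition"
        )
    freqs = model.frequencies
    scored = []
    for hit in hits:
        pep = hit.nonamer if hit.nonamer is not None else hit.octamer
        total = 0.0
        for pos in pep.positions():
            res = pep.residue_at(pos)
            f_model = freqs[AA_INDEX[res], pos - 1]
            if f_model <= 0.0:
                total = -math.inf
                break
            total += math.log2(f_model / background[res])
        scored.append(replace(hit, score=total,
                              curation_flags=set(hit.curation_flags),
                              annotations=dict(hit.annotations)))
    scored.sort(key=lambda h: (-(h.score if h.score != -math.inf else -1e308),
                               h.protein_id, h.start))
    return scored


def expected_background_match_rate(
    motif_or_pattern: RecognitionMotif | SearchPattern,
    residue_frequencies: Mapping[str, float] | None = None,
) -> float:
    """Analytic per-window match probability under an i.i.d. background.

    For a motif: product over constrained positions of the summed
    frequencies of the allowed residues.  For a single pattern: product of
    the frequencies of its non-wildcard symbols.
    """
    if residue_frequencies is None:
        residue_frequencies = UNIFORM_BACKGROUND
    total = sum(residue_frequencies.get(aa, 0.0) for aa in AMINO_ACIDS)
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ScanError(f"residue frequencies sum to {total}, expected 1")
    rate = 1.0
    if isinstance(motif_or_pattern, SearchPattern):
        for sym in motif_or_pattern.pattern:
            if sym != "X":
                rate *= residue_frequencies.get(sym, 0.0)
        return rate
    motif = motif_or_pattern
    for pos in motif.constrained_positions:
        rate *= sum(
            residue_frequencies.get(aa, 0.0) for aa in motif.allowed_residues(pos)
        )
    return rate


def annotate_hla_binding(
    hits: Iterable[MotifHit],
    scorer: Callable[[str], float] | None = None,
) -> list[MotifHit]:
    """Annotate hits with an HLA-C*06:02 binding score or anchor surrogate.

    ``scorer`` is a user-supplied callable (e.g. wrapping an external
    peptide-MHC predictor) mapping a nonamer sequence to a score.  Without
    one, the built-in surrogate checks the HLA anchors directly: P2 = Arg
    and P9 in {L, M, V, F, I}.  A failing scorer annotates the hit
    ``binding_unscored``; hits are never dropped here.
    """
    out = []
    for hit in hits:
        new = replace(hit, curation_flags=set(hit.curation_flags),
                      annotations=dict(hit.annotations))
        if scorer is None:
            p2, p9 = new.residue_at(2), new.residue_at(9)
            new.annotations["anchor_ok"] = (
                p2 == "R" and p9 in set("LMVFI")
            )
        elif new.nonamer is None:
            new.annotations["binding_unscored"] = True
        else:
            try:
                new.annotations["hla_binding_score"] = float(
                    scorer(new.nonamer.sequence)
                )
            except Exception as exc:  # hook failures must never drop hits
                logger.warning(
                    "binding hook failed for %s@%d: %s",
                    new.protein_id, new.start, exc,
                )
                new.annotations["binding_unscored"] = True
        out.append(new)
    return out


def dedup_nonamers(hits: Iterable[MotifHit]) -> dict[str, list[MotifHit]]:
    """Collapse hits sharing an identical completed nonamer (summary view)."""
    groups: dict[str, list[MotifHit]] = {}
    for hit in hits:
        key = hit.nonamer.sequence if hit.nonamer else hit.octamer.sequence
        groups.setdefault(key, []).append(copy.deepcopy(hit))
    return groups


# ---------------------------------------------------------------------------
# Hit table I/O (1-based inclusive coordinates in user-facing TSV)
# ---------------------------------------------------------------------------

HIT_TSV_COLUMNS = (
    "protein_id", "start_1based", "octamer", "nonamer", "p1", "flags", "score"
)


def hits_to_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(HIT_TSV_COLUMNS) + "\n")
        for h in hits:
            out.write("\t".join([
                h.protein_id,
                str(h.start + 1),
                h.octamer.sequence,
                h.nonamer.sequence if h.nonamer else "",
                h.p1_residue or "",
                ",".join(sorted(h.curation_flags)),
                "" if h.score is None else repr(h.score),
            ]) + "\n")


def hits_from_tsv(path: str | Path) -> list[MotifHit]:
    hits = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != HIT_TSV_COLUMNS:
            raise ScanError(f"unexpected hit table header: {header}")
        for line in handle:
            if not line.strip():
                continue
            pid, start1, octamer, nonamer, p1, flags, score = (
                line.rstrip("\n").split("\t")
            )
            hits.append(MotifHit(
                protein_id=pid,
                start=int(start1) - 1,
                octamer=Peptide(octamer),
                nonamer=Peptide(nonamer) if nonamer else None,
                p1_residue=p1 or None,
                curation_flags=set(flags.split(",")) if flags else set(),
                score=float(score) if score else None,
            ))
    return hits
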