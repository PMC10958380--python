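"""TCR recognition-motif modelling.

A class I HLA-presented nonamer is indexed P1..P9.  A polyspecific TCR such
as the psoriatic Va3S1/Vb13S1 receptor reads only a handful of these
positions: HLA anchor residues (P2 and the C-terminal P9, with an auxiliary
anchor at P7) fix the peptide in the HLA-C*06:02 groove, and one or two TCR
contact residues (P5, P8) touch the receptor itself.  All remaining
positions tolerate broad diversity, which is what lets structurally
unrelated environmental peptides cross-activate an autoreactive receptor.

This module turns experimental evidence into an explicit
:class:`RecognitionMotif`:

* alanine-scanning mutagenesis profiles identify the *critical* positions
  (those whose substitution abolishes stimulation),
* a :class:`PositionFrequencyModel` built from stimulatory ligands records
  which residues are tolerated at each position (heat-map / sequence-logo
  numerics), and
* the motif is compiled into degenerate octamer :class:`SearchPattern`
  strings suitable for proteome scanning.

Octamer/nonamer registers: in octamers the NH2-terminal residue occupies
nonamer position P2, i.e. octamer index i (1-based) maps to P(i+1); the P1
residue is absent and must be supplemented from flanking protein sequence.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical one-letter amino-acid alphabet (alphabetical order).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity / non-standard codes that a scanner must not interpret.
AMBIGUOUS_RESIDUES = frozenset("XBZJUO*")

NONAMER_POSITIONS = tuple(range(1, 10))

MAX_COLUMN_BITS = math.log2(20.0)


class MotifError(ValueError):
    """Raised for invalid peptides, motifs or patterns."""


# ---------------------------------------------------------------------------
# Peptides and ligand observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peptide:
    """An octamer or nonamer peptide in nonamer register.

    Octamers start at nonamer position P2 (their NH2-terminus corresponds
    to P2); nonamers cover P1..P9.
    """

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) not in (8, 9):
            raise MotifError(
                f"peptide must be an octamer or nonamer, got length {len(seq)}: {seq!r}"
            )
        bad = set(seq) - AA_SET
        if bad:
            raise MotifError(
                f"invalid residue letter(s) {sorted(bad)} in peptide {seq!r}"
            )

    @property
    def register(self) -> Literal["octamer", "nonamer"]:
        return "nonamer" if len(self.sequence) == 9 else "octamer"

    def positions(self) -> range:
        """Nonamer positions covered by this peptide."""
        return range(1, 10) if self.register == "nonamer" else range(2, 10)

    def residue_at(self, position: int) -> str | None:
        """Residue at nonamer position P1..P9, or None if uncovered (octamer P1)."""
        if position not in NONAMER_POSITIONS:
            raise MotifError(f"nonamer position must be in 1..9, got {position}")
        if self.register == "nonamer":
            return self.sequence[position - 1]
        if position == 1:
            return None
        return self.sequence[position - 2]

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


@dataclass(frozen=True)
class LigandObservation:
    """One tested peptide ligand with its stimulation outcome.

    ``activation`` is the readout relative to CD3 stimulation in the same
    experiment, in [0, 1] with a small overshoot tolerated.
    """

    peptide: Peptide
    source_label: str = ""
    stimulatory: bool = True
    activation: float | None = None

    def __post_init__(self) -> None:
        if self.activation is not None and not (0.0 <= self.activation <= 1.2):
            raise MotifError(
                f"activation must lie in [0, 1.2], got {self.activation}"
            )

    def check_consistency(self, activation_cutoff: float) -> None:
        """Verify the stimulatory flag against an activation cutoff."""
        if self.activation is None:
            return
        if self.stimulatory != (self.activation >= activation_cutoff):
            raise MotifError(
                f"ligand {self.peptide}: stimulatory={self.stimulatory} inconsistent "
                f"with activation {self.activation} at cutoff {activation_cutoff}"
            )


@dataclass(frozen=True)
class AlanineScanProfile:
    """Per-position activation after single-residue substitution.

    Each tested nonamer position maps to the residual activation (fraction
    of CD3-normalised wild-type response) after substituting that position,
    normally with alanine; anchor positions may instead be probed with an
    alternative anchor-residue set.
    """

    base_peptide: Peptide
    activation: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.base_peptide.register != "nonamer":
            raise MotifError("alanine-scan base peptide must be a nonamer")
        acts = dict(self.activation)
        object.__setattr__(self, "activation", acts)
        bad = set(acts) - set(NONAMER_POSITIONS)
        if bad:
            raise MotifError(f"scan positions outside P1..P9: {sorted(bad)}")
        neg = {p: v for p, v in acts.items() if v < 0}
        if neg:
            raise MotifError(f"negative activation values: {neg}")

    @property
    def untested_positions(self) -> frozenset[int]:
        return frozenset(NONAMER_POSITIONS) - set(self.activation)


def infer_critical_positions(
    scan: AlanineScanProfile, abolition_threshold: float = 0.2
) -> set[int]:
    """Positions whose substitution abolishes stimulation.

    A position is critical when its residual activation falls below
    ``abolition_threshold`` (default 0.2 of the CD3-normalised response,
    separating near-zero "abolished" bars from tolerated substitutions).
    Untested positions are reported via a warning, never silently treated
    as critical.
    """
    if not 0.0 < abolition_threshold < 1.0:
        raise MotifError(
            f"abolition_threshold must lie in (0, 1), got {abolition_threshold}"
        )
    if not scan.activation:
        raise MotifError("alanine-scan profile is empty: no positions tested")
    if scan.untested_positions:
        logger.warning(
            "alanine scan of %s left positions untested (not counted critical): %s",
            scan.base_peptide,
            sorted(scan.untested_positions),
        )
    return {p for p, v in scan.activation.items() if v < abolition_threshold}


# ---------------------------------------------------------------------------
# Position frequency model (heat-map / sequence-logo numerics)
# ---------------------------------------------------------------------------

@dataclass
class PositionFrequencyModel:
    """Residue counts and frequencies per nonamer column.

    ``counts`` is a 20 x 9 integer matrix (rows ordered by
    :data:`AMINO_ACIDS`).  Frequencies add ``pseudocount`` to every cell
    before normalising each column to 1.  A column with neither
    observations nor pseudocount is reported as uniform (maximum entropy,
    zero information) — this happens for P1 when all ligands are octamers.
    """

    counts: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (20, 9):
            raise MotifError(f"counts must be 20x9, got {counts.shape}")
        if (counts < 0).any():
            raise MotifError("counts must be non-negative")
        if self.pseudocount < 0:
            raise MotifError("pseudocount must be non-negative")
        self.counts = counts

    @property
    def frequencies(self) -> np.ndarray:
        padded = self.counts + self.pseudocount
        totals = padded.sum(axis=0)
        freqs = np.empty_like(padded)
        for j in range(9):
            if totals[j] == 0:
                freqs[:, j] = 1.0 / 20.0
            else:
                freqs[:, j] = padded[:, j] / totals[j]
        return freqs

    @property
    def information_content(self) -> np.ndarray:
        """Per-column information in bits: log2(20) - Shannon entropy.

        No small-sample correction is applied.
        """
        freqs = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
        entropy = -plogp.sum(axis=0)
        ic = MAX_COLUMN_BITS - entropy
        return np.clip(ic, 0.0, MAX_COLUMN_BITS)

    def column_frequency(self, position: int, residue: str) -> float:
        return float(self.frequencies[AA_INDEX[residue], position - 1])

    def observed_residues(self, position: int) -> dict[str, int]:
        """Residues with at least one raw observation at a position."""
        col = self.counts[:, position - 1]
        return {AMINO_ACIDS[i]: int(col[i]) for i in np.nonzero(col)[0]}


def build_frequency_model(
    ligands: Iterable[LigandObservation | Peptide],
    pseudocount: float = 0.0,
) -> PositionFrequencyModel:
    """Count residues of stimulatory ligands per nonamer column.

    Octamers are lifted into nonamer register (their first residue counts
    toward P2); their unknown P1 contributes nothing.  Non-stimulatory
    :class:`LigandObservation` entries are ignored.
    """
    counts = np.zeros((20, 9), dtype=float)
    n_used = 0
    for entry in ligands:
        if isinstance(entry, LigandObservation):
            if not entry.stimulatory:
                continue
            pep = entry.peptide
        else:
            pep = entry
        for pos in pep.positions():
            res = pep.residue_at(pos)
            counts[AA_INDEX[res], pos - 1] += 1
        n_used += 1
    if n_used == 0:
        raise MotifError("no stimulatory ligands to build a frequency model from")
    return PositionFrequencyModel(counts=counts, pseudocount=pseudocount)


def information_content(model: PositionFrequencyModel) -> np.ndarray:
    """Per-position information content of a frequency model, in bits."""
    return model.information_content


# ---------------------------------------------------------------------------
# Recognition motif
# ---------------------------------------------------------------------------

ConstraintKind = Literal["fixed", "allowed", "free"]

#: Default functional annotation of the five constrained positions.
DEFAULT_POSITION_ROLES: dict[int, str] = {
    2: "HLA anchor",
    5: "TCR contact",
    7: "auxiliary anchor",
    8: "TCR contact",
    9: "HLA anchor",
}


@dataclass(frozen=True)
class PositionConstraint:
    kind: ConstraintKind
    residues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        residues = frozenset(self.residues)
        object.__setattr__(self, "residues", residues)
        if self.kind == "free" and residues:
            raise MotifError("free positions carry no residue set")
        if self.kind == "fixed" and len(residues) != 1:
            raise MotifError("fixed constraint requires exactly one residue")
        if self.kind == "allowed" and not residues:
            raise MotifError("allowed constraint requires a non-empty residue set")
        bad = residues - AA_SET
        if bad:
            raise MotifError(f"invalid residues in constraint: {sorted(bad)}")

    def admits(self, residue: str) -> bool:
        return self.kind == "free" or residue in self.residues


@dataclass(frozen=True)
class MatchVerdict:
    """Outcome of testing a peptide against a motif.

    ``failures`` lists (position, reason) for every position that fails;
    ``untested`` holds constrained positions the peptide does not cover
    (P1 for octamers).
    """

    matched: bool
    failures: tuple[tuple[int, str], ...] = ()
    untested: frozenset[int] = frozenset()

    def __bool__(self) -> bool:
        return self.matched

    @property
    def failing_positions(self) -> set[int]:
        return {pos for pos, _ in self.failures}


@dataclass(frozen=True)
class RecognitionMotif:
    """Per-position constraint model for a TCR recognition motif.

    Every nonamer position carries a constraint (fixed residue, allowed
    residue set, or free); ``forbidden`` optionally bans residues at
    otherwise free positions; ``annotations`` records each position's
    functional role (HLA anchor, auxiliary anchor, TCR contact, neutral).
    """

    constraints: Mapping[int, PositionConstraint]
    forbidden: Mapping[int, frozenset[str]] = field(default_factory=dict)
    annotations: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cons = {p: self.constraints.get(p, PositionConstraint("free"))
                for p in NONAMER_POSITIONS}
        bad = set(self.constraints) - set(NONAMER_POSITIONS)
        if bad:
            raise MotifError(f"constraint positions outside P1..P9: {sorted(bad)}")
        forb = {p: frozenset(v) for p, v in self.forbidden.items()}
        if set(forb) - set(NONAMER_POSITIONS):
            raise MotifError("forbidden positions outside P1..P9")
        for p, v in forb.items():
            if cons[p].kind == "fixed" and cons[p].residues & v:
                raise MotifError(
                    f"P{p}: forbidden set overlaps the fixed residue"
                )
        object.__setattr__(self, "constraints", cons)
        object.__setattr__(self, "forbidden", forb)
        object.__setattr__(self, "annotations", dict(self.annotations))

    @classmethod
    def from_allowed_sets(
        cls,
        allowed: Mapping[int, str | Iterable[str]],
        forbidden: Mapping[int, Iterable[str]] | None = None,
        annotations: Mapping[int, str] | None = None,
    ) -> "RecognitionMotif":
        """Build a motif from {position: residue(s)}; absent positions are free."""
        cons: dict[int, PositionConstraint] = {}
        for pos, residues in allowed.items():
            rset = frozenset(residues)
            kind: ConstraintKind = "fixed" if len(rset) == 1 else "allowed"
            cons[pos] = PositionConstraint(kind, rset)
        return cls(
            constraints=cons,
            forbidden={p: frozenset(v) for p, v in (forbidden or {}).items()},
            annotations=dict(annotations or {}),
        )

    def constraint(self, position: int) -> PositionConstraint:
        return self.constraints[position]

    @property
    def constrained_positions(self) -> tuple[int, ...]:
        return tuple(
            p for p in NONAMER_POSITIONS if self.constraints[p].kind != "free"
        )

    def allowed_residues(self, position: int) -> frozenset[str]:
        """Residues admitted at a position (full alphabet minus forbidden if free)."""
        c = self.constraints[position]
        base = c.residues if c.kind != "free" else AA_SET
        return frozenset(base) - self.forbidden.get(position, frozenset())

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "positions": {
                str(p): {"kind": c.kind, "residues": "".join(sorted(c.residues))}
                for p, c in self.constraints.items()
            },
            "forbidden": {
                str(p): "".join(sorted(v)) for p, v in self.forbidden.items()
            },
            "annotations": {str(p): v for p, v in self.annotations.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RecognitionMotif":
        payload = json.loads(text)
        cons = {
            int(p): PositionConstraint(d["kind"], frozenset(d["residues"]))
            for p, d in payload.get("positions", {}).items()
        }
        forb = {int(p): frozenset(v) for p, v in payload.get("forbidden", {}).items()}
        ann = {int(p): v for p, v in payload.get("annotations", {}).items()}
        return cls(constraints=cons, forbidden=forb, annotations=ann)


def matches(peptide: Peptide | str, motif: RecognitionMotif) -> MatchVerdict:
    """Test a peptide against a recognition motif.

    True iff every constrained position the peptide covers holds an
    admitted residue and no forbidden residue occurs.  Octamers leave P1
    unevaluated (reported in ``untested``).  Failure reasons name every
    failing position.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    failures: list[tuple[int, str]] = []
    untested: set[int] = set()
    for pos in NONAMER_POSITIONS:
        res = peptide.residue_at(pos)
        cons = motif.constraints[pos]
        forb = motif.forbidden.get(pos, frozenset())
        if res is None:
            if cons.kind != "free" or forb:
                untested.add(pos)
            continue
        if not cons.admits(res):
            allowed = "".join(sorted(cons.residues))
            failures.append((pos, f"P{pos}: {res} not in {{{allowed}}}"))
        elif res in forb:
            failures.append((pos, f"P{pos}: {res} forbidden"))
    return MatchVerdict(
        matched=not failures,
        failures=tuple(failures),
        untested=frozenset(untested),
    )


def derive_recognition_motif(
    model: PositionFrequencyModel,
    critical_positions: Iterable[int],
    allowed_fraction_threshold: float = 0.0,
    annotations: Mapping[int, str] | None = None,
    forbidden: Mapping[int, Iterable[str]] | None = None,
) -> RecognitionMotif:
    """Derive a recognition motif from ligand frequencies and critical positions.

    Critical positions become fixed (single observed residue) or allowed
    (every residue observed at least once whose frequency among
    observations is >= ``allowed_fraction_threshold``; the default of 0
    takes the plain observation union).  Non-critical positions stay free.
    """
    critical = sorted(set(critical_positions))
    bad = set(critical) - set(NONAMER_POSITIONS)
    if bad:
        raise MotifError(f"critical positions outside P1..P9: {sorted(bad)}")
    allowed: dict[int, frozenset[str]] = {}
    for pos in critical:
        observed = model.observed_residues(pos)
        total = sum(observed.values())
        if total == 0:
            raise MotifError(
                f"critical position P{pos} has no ligand observations"
            )
        residues = frozenset(
            res for res, n in observed.items()
            if n / total >= allowed_fraction_threshold
        ) if allowed_fraction_threshold > 0 else frozenset(observed)
        if not residues:
            raise MotifError(
                f"critical position P{pos}: no residue reaches frequency "
                f"{allowed_fraction_threshold}"
            )
        allowed[pos] = residues
    roles = dict(annotations) if annotations is not None else {
        p: DEFAULT_POSITION_ROLES.get(p, "neutral") for p in critical
    }
    return RecognitionMotif.from_allowed_sets(
        allowed, forbidden=forbidden, annotations=roles
    )


# ---------------------------------------------------------------------------
# Search patterns
# ---------------------------------------------------------------------------

WILDCARD = "X"


@dataclass(frozen=True)
class SearchPattern:
    """A degenerate octamer search pattern: residue letters plus 'X' wildcards.

    Octamer index i (1-based) corresponds to nonamer position P(i+1).
    ``provenance`` records the (P5, P7, P9) residue combination the pattern
    encodes; ``wildcard_p7`` marks patterns whose P7 slot is a wildcard and
    whose match set therefore exceeds the motif language at P7.
    """

    pattern: str
    provenance: tuple[str, str, str] | None = None
    wildcard_p7: bool = False

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if len(pat) != 8:
            raise MotifError(f"search pattern must have length 8, got {pat!r}")
        bad = set(pat) - AA_SET - {WILDCARD}
        if bad:
            raise MotifError(f"invalid pattern symbols {sorted(bad)} in {pat!r}")

    def symbol_at(self, position: int) -> str:
        """Pattern symbol at nonamer position P2..P9."""
        if not 2 <= position <= 9:
            raise MotifError("octamer patterns cover nonamer positions P2..P9")
        return self.pattern[position - 2]

    def to_regex(self) -> str:
        cls = f"[{AMINO_ACIDS}]"
        return "".join(cls if s == WILDCARD else s for s in self.pattern)

    def matches_octamer(self, octamer: str) -> bool:
        if len(octamer) != 8:
            return False
        return all(
            s == WILDCARD or s == r for s, r in zip(self.pattern, octamer.upper())
        ) and not (set(octamer.upper()) - AA_SET)

    def __str__(self) -> str:
        return self.pattern


#: The eight classic octamer search motifs used to screen protein databases
#: for environmental ligands of the Va3S1/Vb13S1 TCR.
VA3S1_VB13S1_SEARCH_PATTERNS: tuple[str, ...] = (
    "RXXRXXRL",
    "RXXNXRRL",
    "RXXRXRRL",
    "RXXNXLRL",
    "RXXRXLRL",
    "RXXQXLRL",
    "RXXRXLRM",
    "RXXRXRRM",
)


def va3s1_vb13s1_motif() -> RecognitionMotif:
    """The recognition motif of the psoriatic Va3S1/Vb13S1 TCR.

    Five constrained positions: Arg fixed at P2 (HLA-C*06:02 anchor) and P8
    (TCR contact); P5 in {R, N, Q} (TCR contact); P7 in {R, L} (auxiliary
    anchor); P9 in {L, M, V, F, I} (C-terminal HLA anchor).  P1, P3, P4 and
    P6 are free.
    """
    return RecognitionMotif.from_allowed_sets(
        {2: "R", 5: "RNQ", 7: "RL", 8: "R", 9: "LMVFI"},
        annotations=DEFAULT_POSITION_ROLES,
    )


def _pattern_from_combination(
    motif: RecognitionMotif, chosen: Mapping[int, str]
) -> SearchPattern:
    symbols = []
    for pos in range(2, 10):
        c = motif.constraints[pos]
        if c.kind == "fixed":
            symbols.append(next(iter(c.residues)))
        elif c.kind == "allowed":
            symbols.append(chosen[pos])
        else:
            symbols.append(WILDCARD)
    pattern = "".join(symbols)
    prov = tuple(pattern[p - 2] for p in (5, 7, 9))
    return SearchPattern(pattern, provenance=prov,  # type: ignore[arg-type]
                         wildcard_p7=pattern[5] == WILDCARD)


def compile_search_patterns(
    motif: RecognitionMotif,
    combination_policy: Literal["cartesian", "explicit"] = "cartesian",
    explicit_patterns: Sequence[str] | None = None,
) -> list[SearchPattern]:
    """Compile a motif into degenerate octamer search patterns.

    ``cartesian`` emits the full product of allowed residues at every
    variable constrained position (fixed positions print their residue,
    free positions 'X').  ``explicit`` emits exactly the configured pattern
    list after validating each against the motif; a wildcard is licensed at
    a constrained position only at P7, where it is flagged
    (``wildcard_p7``) because its match set exceeds the motif language.
    """
    if motif.constraints[1].kind != "free":
        raise MotifError(
            "octamer patterns cannot express a P1 constraint"
        )
    if combination_policy == "cartesian":
        variable = [
            p for p in range(2, 10) if motif.constraints[p].kind == "allowed"
        ]
        choices = [sorted(motif.constraints[p].residues) for p in variable]
        patterns = []
        for combo in itertools.product(*choices):
            patterns.append(
                _pattern_from_combination(motif, dict(zip(variable, combo)))
            )
        return patterns
    if combination_policy == "explicit":
        if explicit_patterns is None:
            raise MotifError("explicit policy requires a pattern list")
        compiled = []
        for raw in explicit_patterns:
            pat = SearchPattern(raw)
            wildcard_p7 = False
            for pos in range(2, 10):
                sym = pat.symbol_at(pos)
                c = motif.constraints[pos]
                if sym == WILDCARD:
                    if c.kind == "free":
                        continue
                    if pos == 7:
                        wildcard_p7 = True
                        continue
                    raise MotifError(
                        f"pattern {raw!r}: wildcard at constrained position P{pos} "
                        "is not licensed by the motif"
                    )
                if not c.admits(sym):
                    raise MotifError(
                        f"pattern {raw!r}: residue {sym} at P{pos} is not licensed "
                        f"by the motif (allowed: "
                        f"{{{''.join(sorted(c.residues))}}})"
                    )
            prov = tuple(pat.symbol_at(p) for p in (5, 7, 9))
            compiled.append(
                SearchPattern(pat.pattern, provenance=prov,  # type: ignore[arg-type]
                              wildcard_p7=wildcard_p7)
            )
        return compiled
    raise MotifError(f"unknown combination policy {combination_policy!r}")
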