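"""Seeded synthetic data generators for every pipeline stage.

Three generators with recorded ground truth, so scanning, assay statistics
and cohort analysis are each testable end-to-end without any downloads:

* proteomes with i.i.d. background residues and motif-conforming nonamers
  planted at known coordinates,
* stimulation-assay tables with multiplicative group effects and
  log-normal noise (cpm are positive and right-skewed; CD137 percentages
  are clipped to [0, 100]),
* GfD-like cohort tables with configurable response and serology rates.

All randomness flows through numpy's default PCG64 generator seeded from
the config; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord, classify_pasi_improvement
from .motif import AMINO_ACIDS, AA_INDEX, Peptide, RecognitionMotif, va3s1_vb13s1_motif
from .scan import ProteinRecord, UNIFORM_BACKGROUND
from .stats import StimulationRecord

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    """Raised for invalid simulation configs (e.g. planting collisions)."""


# ---------------------------------------------------------------------------
# Proteome generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInstance:
    """One motif instance to plant: verbatim nonamer or motif-sampled.

    ``protein_index`` and ``offset`` (0-based nonamer start) may be left
    None for random placement.
    """

    sequence: str | None = None
    protein_index: int | None = None
    offset: int | None = None


@dataclass(frozen=True)
class ProteomeSimConfig:
    seed: int
    n_proteins: int = 50
    length_range: tuple[int, int] = (200, 600)
    background: Mapping[str, float] | None = None  # default uniform 1/20
    planted: int | Sequence[PlantedInstance] = 0
    motif: RecognitionMotif | None = None  # sampling source for planted nonamers
    avoid_forbidden: Mapping[int, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (9 <= lo <= hi):
            raise SimulationError("length range must satisfy 9 <= min <= max")
        if self.background is not None:
            total = sum(self.background.values())
            if abs(total - 1.0) > 1e-6:
                raise SimulationError(
                    f"background frequencies sum to {total}, expected 1"
                )


def _background_probs(background: Mapping[str, float] | None) -> np.ndarray:
    freqs = background if background is not None else UNIFORM_BACKGROUND
    probs = np.array([freqs.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    return probs / probs.sum()


def sample_motif_nonamer(
    motif: RecognitionMotif,
    rng: np.random.Generator,
    avoid_forbidden: Mapping[int, frozenset[str]] | None = None,
) -> str:
    """Draw a nonamer uniformly from the motif language.

    Constrained positions draw uniformly from their allowed set, free
    positions from the full alphabet; residues in ``avoid_forbidden`` (on
    top of the motif's own forbidden sets) are excluded.
    """
    avoid = avoid_forbidden or {}
    chars = []
    for pos in range(1, 10):
        admitted = sorted(
            motif.allowed_residues(pos) - frozenset(avoid.get(pos, frozenset()))
        )
        if not admitted:
            raise SimulationError(f"P{pos}: no residue left to sample")
        chars.append(admitted[int(rng.integers(len(admitted)))])
    return "".join(chars)


def generate_proteome(
    config: ProteomeSimConfig,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a synthetic proteome and the truth table of planted motifs.

    Background residues are i.i.d. from the configured composition.
    Planted nonamers (verbatim or sampled from the motif language) are
    written over the background at recorded coordinates; overlapping
    planted windows raise :class:`SimulationError`.  The truth table holds
    one row per planted instance with 0-based nonamer and octamer starts.
    """
    rng = np.random.default_rng(config.seed)
    probs = _background_probs(config.background)
    aa_array = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    sequences = [
        rng.choice(aa_array, size=int(n), p=probs).tobytes().decode()
        for n in lengths
    ]
    seq_arrays = [list(s) for s in sequences]

    if isinstance(config.planted, int):
        motif = config.motif if config.motif is not None else va3s1_vb13s1_motif()
        plan = [PlantedInstance() for _ in range(config.planted)]
    else:
        motif = config.motif if config.motif is not None else va3s1_vb13s1_motif()
        plan = list(config.planted)

    occupied: dict[int, list[tuple[int, int]]] = {}
    truth_rows = []
    for k, inst in enumerate(plan):
        seq = inst.sequence
        if seq is None:
            seq = sample_motif_nonamer(motif, rng, config.avoid_forbidden)
        else:
            seq = str(Peptide(seq))
            if len(seq) != 9:
                raise SimulationError("planted sequences must be nonamers")
        if inst.protein_index is not None:
            p_idx, offset = inst.protein_index, inst.offset
            if offset is None:
                raise SimulationError(
                    "explicit protein_index requires an explicit offset"
                )
            if not (0 <= offset <= len(seq_arrays[p_idx]) - 9):
                raise SimulationError(
                    f"planted offset {offset} outside protein {p_idx}"
                )
            if any(offset < e and s < offset + 9
                   for s, e in occupied.get(p_idx, [])):
                raise SimulationError(
                    f"planting collision in protein {p_idx} at offset {offset}"
                )
        else:
            placed = False
            for _ in range(200):
                p_idx = int(rng.integers(config.n_proteins))
                room = len(seq_arrays[p_idx]) - 9
                if room < 0:
                    continue
                offset = int(rng.integers(room + 1))
                if not any(offset < e and s < offset + 9
                           for s, e in occupied.get(p_idx, [])):
                    placed = True
                    break
            if not placed:
                raise SimulationError(
                    "could not place planted instance without collision"
                )
        seq_arrays[p_idx][offset:offset + 9] = list(seq)
        occupied.setdefault(p_idx, []).append((offset, offset + 9))
        truth_rows.append({
            "planted_id": k,
            "protein_index": p_idx,
            "protein_id": f"synth|{p_idx:04d}",
            "nonamer_start": offset,
            "octamer_start": offset + 1,
            "nonamer": seq,
        })

    proteins = [
        ProteinRecord(
            id=f"synth|{i:04d}",
            description=f"synth|{i:04d} synthetic background protein",
            sequence="".join(arr),
        )
        for i, arr in enumerate(seq_arrays)
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=["planted_id", "protein_index", "protein_id",
                 "nonamer_start", "octamer_start", "nonamer"],
    )
    return proteins, truth


def recovered_fraction(hits: Sequence, truth: pd.DataFrame) -> float:
    """Fraction of planted instances present in a hit list (sensitivity).

    A planted instance counts as recovered when some hit lies at its
    octamer coordinate in the right protein.
    """
    if len(truth) == 0:
        return 1.0
    found = {(h.protein_id, h.start) for h in hits}
    hit_count = sum(
        (row.protein_id, row.octamer_start) in found
        for row in truth.itertuples()
    )
    return hit_count / len(truth)


def count_matching_windows(
    motif: RecognitionMotif,
    n_windows: int,
    seed: int,
    frequencies: Mapping[str, float] | None = None,
    chunk_size: int = 1_000_000,
) -> int:
    """Count motif matches among i.i.d. random nonamer windows (vectorised).

    Draws ``n_windows`` independent nonamers from the given residue
    composition and counts those accepted at every constrained position —
    the empirical counterpart of
    :func:`mimoscan.scan.expected_background_match_rate`.
    """
    rng = np.random.default_rng(seed)
    probs = _background_probs(frequencies)
    masks = {}
    for pos in motif.constrained_positions:
        mask = np.zeros(20, dtype=bool)
        for aa in motif.allowed_residues(pos):
            mask[AA_INDEX[aa]] = True
        masks[pos] = mask
    total = 0
    remaining = n_windows
    while remaining > 0:
        n = min(chunk_size, remaining)
        windows = rng.choice(20, size=(n, 9), p=probs)
        ok = np.ones(n, dtype=bool)
        for pos, mask in masks.items():
            ok &= mask[windows[:, pos - 1]]
        total += int(ok.sum())
        remaining -= n
    return total


# ---------------------------------------------------------------------------
# Assay generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssaySimConfig:
    """Stimulation-assay simulation mirroring the study's group contrast.

    Defaults correspond to the proliferation arm of the study conditions:
    41 psoriasis patients vs 12 healthy controls, cpm triplicates with one
    unstimulated control triplicate per subject, and a 3-fold stimulation
    effect in patients for a wheat-like peptide.  ``effects`` maps peptide
    label -> group -> multiplicative effect (> 0).
    """

    seed: int
    n_pso: int = 41
    n_hc: int = 12
    effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"wheat-1": {"Pso": 3.0, "HC": 1.0}}
    )
    readout: str = "cpm_triplicate"
    control_mean: float = 200.0
    sigma_between: float = 0.6
    sigma_within: float = 0.25
    n_stim_reps: int = 3
    n_ctrl_reps: int = 3

    def __post_init__(self) -> None:
        for pep, by_group in self.effects.items():
            for grp, eff in by_group.items():
                if eff <= 0:
                    raise SimulationError(
                        f"effect for {pep}/{grp} must be > 0, got {eff}"
                    )
        if self.sigma_between <= 0 or self.sigma_within <= 0:
            raise SimulationError("noise sigmas must be > 0")


def generate_assay_dataset(
    config: AssaySimConfig,
) -> tuple[list[StimulationRecord], pd.DataFrame]:
    """Generate per-subject stimulation records plus the effect truth table.

    Each subject draws a log-normal baseline (between-subject sigma);
    control replicates scatter around it and stimulated replicates around
    baseline x group effect (within-subject sigma), so the stimulation
    index estimates the planted multiplicative effect.  CD137-style
    percentage readouts are clipped to [0, 100].
    """
    rng = np.random.default_rng(config.seed)
    subjects = (
        [("Pso", f"Pso{i+1:03d}") for i in range(config.n_pso)]
        + [("HC", f"HC{i+1:03d}") for i in range(config.n_hc)]
    )
    is_percent = config.readout == "cd137_duplicate"
    records = []
    truth_rows = []
    for group, subject_id in subjects:
        baseline = config.control_mean * rng.lognormal(0.0, config.sigma_between)
        for peptide, by_group in config.effects.items():
            effect = by_group.get(group, 1.0)
            ctrl = baseline * rng.lognormal(
                0.0, config.sigma_within, size=config.n_ctrl_reps
            )
            stim = baseline * effect * rng.lognormal(
                0.0, config.sigma_within, size=config.n_stim_reps
            )
            if is_percent:
                ctrl = np.clip(ctrl, 0.0, 100.0)
                stim = np.clip(stim, 0.0, 100.0)
            records.append(StimulationRecord(
                subject_id=subject_id,
                group=group,
                peptide_label=peptide,
                readout=config.readout,  # type: ignore[arg-type]
                stimulated_values=tuple(stim),
                control_values=tuple(ctrl),
            ))
            truth_rows.append({
                "subject_id": subject_id,
                "group": group,
                "peptide": peptide,
                "true_effect": effect,
            })
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """GfD-like cohort simulation.

    Default rates mirror the observed case series (13 patients, 7/13
    responders, serology positivity 8/13 independent of response).
    Serology positivity may be made response-dependent via distinct
    probabilities.
    """

    seed: int
    n_patients: int = 13
    response_prob: float = 7 / 13
    p_elevated_responder: float = 8 / 13
    p_elevated_nonresponder: float = 8 / 13
    relapse_prob_responder: float = 2 / 7
    psa_prob: float = 3 / 13
    psa_improves_prob: float = 2 / 3
    pasi90_given_response_prob: float = 4 / 7

    def __post_init__(self) -> None:
        for name in ("response_prob", "p_elevated_responder",
                     "p_elevated_nonresponder", "relapse_prob_responder",
                     "psa_prob", "psa_improves_prob",
                     "pasi90_given_response_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")


def generate_cohort_table(
    config: CohortSimConfig,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate synthetic patient records plus the response/serology truth."""
    rng = np.random.default_rng(config.seed)
    records = []
    truth_rows = []
    for i in range(config.n_patients):
        responder = bool(rng.random() < config.response_prob)
        p_elev = (config.p_elevated_responder if responder
                  else config.p_elevated_nonresponder)
        elevated = bool(rng.random() < p_elev)
        # titers straddle the 10 U/ml threshold on the matching side
        combined = float(np.round(
            10.0 + rng.lognormal(0.7, 0.5) if elevated
            else 10.0 - rng.uniform(0.1, 9.5), 1
        ))
        iga = float(np.round(rng.uniform(0.5, combined), 1))
        has_psa = bool(rng.random() < config.psa_prob)
        ctype = frozenset({"PsO", "PsA"}) if has_psa else frozenset({"PsO"})
        if responder:
            pasi_class = ("PASI90"
                          if rng.random() < config.pasi90_given_response_prob
                          else "PASI75")
            relapse = ("Yes" if rng.random() < config.relapse_prob_responder
                       else "NR")
        else:
            pasi_class = "NI"
            relapse = "NR"
        if has_psa:
            psa_impr = ("Yes" if responder
                        and rng.random() < config.psa_improves_prob else "NI")
        else:
            psa_impr = "not_applicable"
        onset = float(rng.integers(5, 55))
        records.append(PatientRecord(
            patient_id=str(i + 1),
            sex="F" if rng.random() < 0.3 else "M",
            clinical_type=ctype,
            age_of_onset=onset,
            gliadin_screen="pos" if elevated else "neg",
            igg_plus_iga=combined,
            iga=iga,
            age_at_gfd=onset + float(rng.integers(5, 40)),
            treatment="synthetic",
            pasi_baseline=float(np.round(rng.uniform(8.0, 30.0), 1)),
            pasi_improvement_class=pasi_class,
            psa_improvement=psa_impr,
            relapse_on_dietary_error=relapse,
        ))
        truth_rows.append({
            "patient_id": str(i + 1),
            "true_responder": responder,
            "true_elevated": elevated,
        })
    return records, pd.DataFrame(truth_rows)


def verify_pasi_class(baseline: float, follow_up: float, expected: str) -> bool:
    """Cross-check a printed improvement class against raw PASI values."""
    from .cohort import pasi_percent_improvement

    return classify_pasi_improvement(
        pasi_percent_improvement(baseline, follow_up)
    ) == expected
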