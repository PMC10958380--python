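"""Shared fixtures: the canonical TCR motif, a synthetic ligand family and
an alanine-scan profile with the expected critical-position structure."""

import pytest

from mimoscan.motif import (
    AlanineScanProfile,
    LigandObservation,
    Peptide,
    va3s1_vb13s1_motif,
)

# Published environmental ligands / control peptide of the Va3S1/Vb13S1 TCR.
WHEAT1 = "LRMRRCRRM"
WHEAT2 = "VRAGRVLRV"
FALK = "VRHDGGNVL"

# Synthetic mimotopes completing coverage of the motif's allowed sets.
SYNTHETIC_MIMOTOPES = ["ARAANALRL", "GRGGQGRRF", "SRSSRSLRI"]


@pytest.fixture(scope="session")
def canonical_motif():
    return va3s1_vb13s1_motif()


@pytest.fixture(scope="session")
def ligand_family():
    """Stimulatory ligand family whose observation union spans the motif."""
    stim = [WHEAT1, WHEAT2] + SYNTHETIC_MIMOTOPES
    ligands = [
        LigandObservation(peptide=Peptide(s), stimulatory=True, activation=0.8)
        for s in stim
    ]
    ligands.append(
        LigandObservation(peptide=Peptide(FALK), stimulatory=False, activation=0.02)
    )
    return ligands


@pytest.fixture(scope="session")
def alanine_profile():
    """Substitution profile: anchors/contacts abolished, P1/P3/P4/P6 intact."""
    return AlanineScanProfile(
        base_peptide=Peptide("ARAARALRL"),
        activation={1: 0.95, 2: 0.02, 3: 0.90, 4: 1.0,
                    5: 0.01, 6: 0.85, 7: 0.00, 8: 0.03, 9: 0.05},
    )
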