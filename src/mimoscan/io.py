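"""Table, pattern and configuration I/O.

Delimited-text readers and writers for ligand/mutagenesis tables, search
pattern files (one pattern per line, with a PROSITE-bracket dialect for
interoperability), background compositions, YAML configs and the
machine-readable provenance blocks that every CLI run emits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from importlib import resources

from .motif import (
    AMINO_ACIDS,
    AlanineScanProfile,
    LigandObservation,
    MotifError,
    Peptide,
    PositionFrequencyModel,
    RecognitionMotif,
    SearchPattern,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ligand and alanine-scan tables
# ---------------------------------------------------------------------------

def read_ligand_table(
    path: str | Path, activation_cutoff: float | None = None
) -> list[LigandObservation]:
    """Read a tab-separated ligand table.

    Columns: sequence, register (octamer|nonamer, checked against length),
    stimulatory (true/false), activation (optional fraction of the CD3
    response), and optionally source.  When ``activation_cutoff`` is
    given, each row's stimulatory flag is checked against it.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"sequence", "register", "stimulatory"}
    missing = required - set(df.columns)
    if missing:
        raise MotifError(f"ligand table missing column(s): {sorted(missing)}")
    ligands = []
    for _, row in df.iterrows():
        pep = Peptide(row["sequence"].strip())
        declared = row["register"].strip().lower()
        if declared and declared != pep.register:
            raise MotifError(
                f"ligand {pep}: declared register {declared!r} does not match "
                f"length {len(pep)}"
            )
        activation = row.get("activation", "")
        obs = LigandObservation(
            peptide=pep,
            source_label=row.get("source", "").strip(),
            stimulatory=row["stimulatory"].strip().lower() in ("true", "1", "yes"),
            activation=float(activation) if activation.strip() else None,
        )
        if activation_cutoff is not None:
            obs.check_consistency(activation_cutoff)
        ligands.append(obs)
    return ligands


def read_scan_table(path: str | Path, base_peptide: str) -> AlanineScanProfile:
    """Read an alanine-scan table: columns position, residue, activation.

    ``residue`` is the substituted residue.  When several substitutions
    were tested at one position (anchor-exchange sets), the alanine row is
    used if present, otherwise the minimum residual activation.  The
    scanned nonamer itself is supplied by configuration, never inferred.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"position", "residue", "activation"}
    missing = required - set(df.columns)
    if missing:
        raise MotifError(f"scan table missing column(s): {sorted(missing)}")
    activation: dict[int, float] = {}
    for pos, sub in df.groupby("position"):
        pos = int(pos)
        ala = sub[sub["residue"].str.strip().str.upper() == "A"]
        value = float(ala["activation"].iloc[0]) if len(ala) else float(
            sub["activation"].min()
        )
        activation[pos] = value
    return AlanineScanProfile(
        base_peptide=Peptide(base_peptide), activation=activation
    )


# ---------------------------------------------------------------------------
# Pattern files (plain and PROSITE dialects)
# ---------------------------------------------------------------------------

def read_patterns(path: str | Path) -> list[str]:
    """Read search patterns, one per line; '#' comments and blanks ignored.

    PROSITE-style lines (containing '-') are converted to the plain
    letters-plus-X dialect.
    """
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "-" in line:
            line = pattern_from_prosite(line)
        patterns.append(line)
    return patterns


def write_patterns(
    patterns: Iterable[SearchPattern | str],
    path: str | Path,
    dialect: str = "plain",
) -> None:
    with open(path, "w") as out:
        for p in patterns:
            text = str(p)
            if dialect == "prosite":
                text = prosite_from_pattern(text)
            out.write(text + "\n")


def prosite_from_pattern(pattern: str) -> str:
    """Plain pattern -> PROSITE dialect (X -> x, '-'-separated, '.'-ended)."""
    elements = []
    for sym in pattern:
        elements.append("x" if sym == "X" else sym)
    # collapse runs of x into x(n)
    collapsed: list[str] = []
    for el in elements:
        if el == "x" and collapsed and collapsed[-1].startswith("x"):
            prev = collapsed.pop()
            n = 1 if prev == "x" else int(prev[2:-1])
            collapsed.append(f"x({n + 1})")
        else:
            collapsed.append(el)
    return "-".join(collapsed) + "."


_PROSITE_ELEMENT = re.compile(
    r"^(?:(?P<res>[A-Za-z])|\[(?P<set>[A-Za-z]+)\]|(?P<any>x)(?:\((?P<rep>\d+)\))?)$"
)


def pattern_from_prosite(text: str) -> str:
    """PROSITE dialect -> plain pattern.

    Supports residues, x / x(n) wildcards, and singleton brackets;
    multi-residue brackets cannot be expressed in a single plain pattern
    and raise :class:`MotifError`.
    """
    text = text.strip().rstrip(".")
    symbols = []
    for element in text.split("-"):
        m = _PROSITE_ELEMENT.match(element.strip())
        if not m:
            raise MotifError(f"cannot parse PROSITE element {element!r}")
        if m.group("res"):
            symbols.append(m.group("res").upper())
        elif m.group("set"):
            residues = m.group("set").upper()
            if len(residues) == 1:
                symbols.append(residues)
            else:
                raise MotifError(
                    f"bracket set [{residues}] needs one pattern per member; "
                    "expand before import"
                )
        else:
            symbols.extend("X" * int(m.group("rep") or 1))
    return "".join(symbols)


def motif_to_prosite(motif: RecognitionMotif, register: str = "nonamer") -> str:
    """Render a motif as a PROSITE-style string (with bracket sets)."""
    positions = range(1, 10) if register == "nonamer" else range(2, 10)
    elements = []
    for pos in positions:
        c = motif.constraints[pos]
        if c.kind == "fixed":
            elements.append(next(iter(c.residues)))
        elif c.kind == "allowed":
            elements.append(f"[{''.join(sorted(c.residues))}]")
        else:
            elements.append("x")
    collapsed: list[str] = []
    for el in elements:
        if el == "x" and collapsed and collapsed[-1].startswith("x"):
            prev = collapsed.pop()
            n = 1 if prev == "x" else int(prev[2:-1])
            collapsed.append(f"x({n + 1})")
        else:
            collapsed.append(el)
    return "-".join(collapsed) + "."


# ---------------------------------------------------------------------------
# Logo / frequency-model tables
# ---------------------------------------------------------------------------

def logo_table(model: PositionFrequencyModel) -> pd.DataFrame:
    """Frequencies plus per-column information content as a tidy table."""
    freqs = model.frequencies
    ic = model.information_content
    rows = []
    for pos in range(1, 10):
        for i, aa in enumerate(AMINO_ACIDS):
            rows.append({
                "position": pos,
                "residue": aa,
                "count": int(model.counts[i, pos - 1]),
                "frequency": float(freqs[i, pos - 1]),
                "information_bits": float(ic[pos - 1]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Background compositions and configs
# ---------------------------------------------------------------------------

def load_background(path: str | Path) -> dict[str, float]:
    """Load a residue composition (YAML mapping), normalised to sum 1."""
    raw = yaml.safe_load(Path(path).read_text())
    comp = {str(k).upper(): float(v) for k, v in raw.items()}
    bad = set(comp) - set(AMINO_ACIDS)
    if bad:
        raise MotifError(f"unknown residues in composition: {sorted(bad)}")
    total = sum(comp.values())
    if total <= 0:
        raise MotifError("composition must have positive total")
    return {aa: comp.get(aa, 0.0) / total for aa in AMINO_ACIDS}


def swissprot_like_background() -> dict[str, float]:
    """The shipped Swiss-Prot-average residue composition."""
    path = resources.files("mimoscan").joinpath("data/swissprot_composition.yaml")
    return load_background(Path(str(path)))


def reference_ligands_path() -> Path:
    """Shipped ligand table: published wheat ligands plus synthetic mimotopes."""
    return Path(str(resources.files("mimoscan").joinpath(
        "data/reference_ligands.tsv"
    )))


def load_yaml_config(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    return data or {}


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def write_provenance(
    out_path: str | Path,
    command: str,
    params: Mapping,
    seed: int | None = None,
    config_paths: Sequence[str | Path] = (),
) -> None:
    """Write a machine-readable provenance block next to an output file.

    Contains the command, parameters, seed, package version and a SHA-256
    digest of every referenced config file — enough to reproduce the run.
    """
    from . import __version__

    digests = {}
    for p in config_paths:
        p = Path(p)
        if p.exists():
            digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    block = {
        "command": command,
        "parameters": {k: str(v) for k, v in params.items()},
        "seed": seed,
        "config_sha256": digests,
        "mimoscan_version": __version__,
    }
    prov_path = Path(str(out_path) + ".provenance.json")
    prov_path.write_text(json.dumps(block, indent=2, sort_keys=True) + "\n")
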