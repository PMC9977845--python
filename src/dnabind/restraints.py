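"""Distance restraints for DNA-ligand complexes.

Two families of restraints are built here for use by external molecular
dynamics engines:

- **NOE-derived** restraints: intermolecular NOESY cross-peaks between
  ligand protons and DNA protons, classified weak/medium/strong by
  cross-peak integration, become atom-pair distance bounds.  The default
  calibration uses conventional NOE-intensity bands — a common lower
  bound of 0.18 nm (van der Waals contact) and upper bounds of 0.29
  (strong), 0.40 (medium) and 0.55 nm (weak) — with a +0.10 nm
  pseudo-atom correction on the upper bound for degenerate methyl groups.

- **Watson-Crick hydrogen-bond** restraints that stabilize base pairing:
  three donor-acceptor restraints per G.C pair (G O6/N1/N2 to C N4/N3/O2)
  and two per A.T pair (A N6/N1 to T O4/N3).  Terminal base pairs, whose
  imino protons exchange too fast to be observed, are excluded by
  default.

The restraining potential is flat-bottomed: zero between the lower and
upper bound and a quadratic penalty 0.5*k*(excess)^2 outside, with a
default force constant of 1000 kJ mol^-1 nm^-2 for every restraint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ParseError, ValidationError
from .seqsteps import DuplexSequence

logger = logging.getLogger(__name__)

DEFAULT_FORCE_CONSTANT = 1000.0  # kJ mol^-1 nm^-2

#: class -> (lower bound nm, upper bound nm); common lower bound, upper
#: bounds widening with decreasing cross-peak intensity.
DEFAULT_CALIBRATION: dict[str, tuple[float, float]] = {
    "strong": (0.18, 0.29),
    "medium": (0.18, 0.40),
    "weak": (0.18, 0.55),
}

#: +0.10 nm on the upper bound for contacts involving a methyl group
#: (degenerate protons represented by a pseudo-atom).
METHYL_CORRECTION_NM = 0.10

#: Watson-Crick donor/acceptor heavy-atom pairs, purine atom first.
WC_HBOND_ATOMS: dict[str, list[tuple[str, str]]] = {
    "GC": [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    "AT": [("N6", "O4"), ("N1", "N3")],
}

INTENSITY_CLASSES = ("weak", "medium", "strong")

__all__ = [
    "NOEContact",
    "DistanceRestraint",
    "parse_noe_table",
    "noe_to_restraints",
    "wc_hbond_restraints",
    "flat_bottom_energy",
    "total_restraint_energy",
    "write_restraints",
]


@dataclass(frozen=True)
class NOEContact:
    """One NOESY cross-peak row: a ligand-proton/DNA-proton contact with a
    per-complex intensity class (the same contact may be medium in one
    complex and weak in another)."""

    ligand_proton: str
    dna_proton: str
    intensity_by_complex: Mapping[str, str]  # complex id -> class

    def __post_init__(self) -> None:
        for cx, cls in self.intensity_by_complex.items():
            if cls not in INTENSITY_CLASSES:
                raise ValidationError(
                    f"unknown intensity class {cls!r} for complex {cx!r}"
                )

    @property
    def present_in(self) -> frozenset[str]:
        return frozenset(self.intensity_by_complex)

    def intensity(self, complex_id: str) -> str:
        return self.intensity_by_complex[complex_id]


@dataclass(frozen=True)
class DistanceRestraint:
    """A flat-bottom distance restraint between two labelled atoms."""

    atom_i: str
    atom_j: str
    low: float  # nm
    up: float  # nm
    k: float = DEFAULT_FORCE_CONSTANT  # kJ mol^-1 nm^-2
    provenance: str = "noe_medium"  # noe_{strong,medium,weak} | wc_hbond

    def __post_init__(self) -> None:
        if not 0 < self.low < self.up:
            raise ValidationError(
                f"require 0 < low < up, got low={self.low}, up={self.up}"
            )
        if not self.k > 0:
            raise ValidationError("force constant must be positive")


def _parse_cell(cell: str, row_no: int, col: str) -> str | None:
    """Parse a presence/intensity cell: '+ (class)', bare class word, or
    an absence dash.  Returns the class or None for absent."""
    text = cell.strip()
    if text in {"-", "–", "—", ""}:
        return None
    low = text.lower()
    if low.startswith("+"):
        low = low[1:].strip()
        if low.startswith("(") and low.endswith(")"):
            low = low[1:-1].strip()
        else:
            raise ParseError(
                f"row {row_no}, column {col!r}: malformed cell {cell!r} "
                "(expected '+ (class)')"
            )
    if low not in INTENSITY_CLASSES:
        raise ParseError(
            f"row {row_no}, column {col!r}: unknown intensity class {cell!r}"
        )
    return low


def parse_noe_table(rows: Iterable[str] | str) -> list[NOEContact]:
    """Parse a TSV NOE contact table into contacts.

    Expected columns: ``ligand_proton``, ``dna_proton``, then one column
    per complex (header = complex id) whose cells are ``+ (class)``, a
    bare class word, or a dash for absent.  Rows absent from every
    complex are retained (with empty presence) so that table bookkeeping
    stays faithful; they are simply never emitted as restraints.
    """
    if isinstance(rows, str):
        rows = rows.splitlines()
    lines = [ln.rstrip("\n") for ln in rows if ln.strip()]
    if not lines:
        return []
    header = [h.strip() for h in lines[0].split("\t")]
    if header[:2] != ["ligand_proton", "dna_proton"]:
        raise ParseError(
            "NOE table must start with columns ligand_proton, dna_proton; "
            f"got {header[:2]}"
        )
    complexes = header[2:]
    if not complexes:
        raise ParseError("NOE table has no complex columns")
    contacts: list[NOEContact] = []
    for row_no, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) != len(header):
            raise ParseError(
                f"row {row_no}: expected {len(header)} columns, got {len(cells)}"
            )
        intensity: dict[str, str] = {}
        for cx, cell in zip(complexes, cells[2:]):
            cls = _parse_cell(cell, row_no, cx)
            if cls is not None:
                intensity[cx] = cls
        contacts.append(
            NOEContact(
                ligand_proton=cells[0],
                dna_proton=cells[1],
                intensity_by_complex=intensity,
            )
        )
    return contacts


def _is_methyl(label: str) -> bool:
    return label.upper().replace("_", "").rstrip("′″'\"").endswith("CH3")


def noe_to_restraints(
    contacts: Iterable[NOEContact],
    complex_id: str,
    calibration: Mapping[str, tuple[float, float]] | None = None,
    k: float = DEFAULT_FORCE_CONSTANT,
    methyl_correction: float = METHYL_CORRECTION_NM,
) -> list[DistanceRestraint]:
    """Distance restraints for the contacts observed in one complex.

    One restraint per contact present in ``complex_id``, bounds taken
    from that complex's intensity class via ``calibration``; output order
    follows the table order.  Contacts involving a methyl pseudo-atom get
    ``methyl_correction`` added to the upper bound.
    """
    cal = dict(calibration) if calibration is not None else DEFAULT_CALIBRATION
    out: list[DistanceRestraint] = []
    for contact in contacts:
        if complex_id not in contact.present_in:
            continue
        cls = contact.intensity(complex_id)
        if cls not in cal:
            raise ValidationError(
                f"calibration has no bounds for class {cls!r}"
            )
        low, up = cal[cls]
        if _is_methyl(contact.ligand_proton) or _is_methyl(contact.dna_proton):
            up += methyl_correction
        out.append(
            DistanceRestraint(
                atom_i=contact.ligand_proton,
                atom_j=contact.dna_proton,
                low=low, up=up, k=k,
                provenance=f"noe_{cls}",
            )
        )
    return out


def wc_hbond_restraints(
    duplex: DuplexSequence | str,
    exclude_terminal: bool = True,
    low: float = 0.27,
    up: float = 0.31,
    k: float = DEFAULT_FORCE_CONSTANT,
) -> list[DistanceRestraint]:
    """Watson-Crick hydrogen-bond restraints for a palindromic duplex.

    Three donor-acceptor restraints per G.C pair and two per A.T pair;
    both terminal base pairs are skipped when ``exclude_terminal`` (their
    imino protons are typically unobservable due to fraying).  The
    default bounds bracket canonical N/O...N/O hydrogen-bond heavy-atom
    distances (~0.28-0.30 nm).  Atom labels carry strand (A/B), residue
    (1-based) and atom name, e.g. ``B:C7:N3``.
    """
    if isinstance(duplex, str):
        duplex = DuplexSequence(duplex)
    out: list[DistanceRestraint] = []
    L = duplex.length
    for i in range(L):
        if exclude_terminal and duplex.is_terminal(i):
            continue
        base_a, base_b = duplex.base_pair(i)
        # orient so the purine's atoms come first
        if base_a in "AG":
            purine, pyrimidine = base_a, base_b
            pur_label = f"A:{base_a}{i + 1}"
            pyr_label = f"B:{base_b}{L - i}"
        else:
            purine, pyrimidine = base_b, base_a
            pur_label = f"B:{base_b}{L - i}"
            pyr_label = f"A:{base_a}{i + 1}"
        key = "GC" if purine == "G" else "AT"
        for pur_atom, pyr_atom in WC_HBOND_ATOMS[key]:
            out.append(
                DistanceRestraint(
                    atom_i=f"{pur_label}:{pur_atom}",
                    atom_j=f"{pyr_label}:{pyr_atom}",
                    low=low, up=up, k=k,
                    provenance="wc_hbond",
                )
            )
    return out


def flat_bottom_energy(r: float, low: float, up: float,
                       k: float = DEFAULT_FORCE_CONSTANT) -> float:
    """Flat-bottom quadratic restraint energy (kJ/mol) at distance ``r``.

    Zero for ``low <= r <= up``; ``0.5*k*(r - up)**2`` above and
    ``0.5*k*(low - r)**2`` below.  C1-continuous at both thresholds.
    """
    if not 0 < low < up:
        raise ValidationError(f"require 0 < low < up, got {low}, {up}")
    if not k > 0:
        raise ValidationError("force constant must be positive")
    if r < 0:
        raise ValidationError("distance must be non-negative")
    if r > up:
        return 0.5 * k * (r - up) ** 2
    if r < low:
        return 0.5 * k * (low - r) ** 2
    return 0.0


def total_restraint_energy(
    distances: Mapping[DistanceRestraint, float] | Mapping[tuple[str, str], float],
    restraints: Iterable[DistanceRestraint],
) -> tuple[float, list[tuple[DistanceRestraint, float, float]]]:
    """Total flat-bottom energy of a restraint set at given distances.

    ``distances`` maps either restraint objects or ``(atom_i, atom_j)``
    pairs to distances in nm.  Returns ``(total, violations)`` where
    ``violations`` lists ``(restraint, distance, energy)`` for every
    restraint with nonzero energy, sorted by energy descending.
    """
    total = 0.0
    violations: list[tuple[DistanceRestraint, float, float]] = []
    for rest in restraints:
        if rest in distances:
            d = distances[rest]
        elif (rest.atom_i, rest.atom_j) in distances:
            d = distances[(rest.atom_i, rest.atom_j)]
        else:
            raise ValidationError(
                f"no distance provided for restraint {rest.atom_i}-{rest.atom_j}"
            )
        e = flat_bottom_energy(d, rest.low, rest.up, rest.k)
        total += e
        if e > 0:
            violations.append((rest, d, e))
    violations.sort(key=lambda t: t[2], reverse=True)
    return total, violations


def write_restraints(
    restraints: list[DistanceRestraint], dialect: str = "tsv"
) -> str:
    """Serialize restraints as text.

    ``tsv``: header plus one row per restraint with all fields.
    ``gromacs-itp-like``: a ``[ distance_restraints ]`` block (columns
    ai aj funct index type low up1 up2 fac) preceded by a commented label
    map from placeholder atom indices to the string labels; ``up2`` is
    ``up1 + 0.1`` nm (the onset of the linear regime in engines that use
    one).  Output is byte-stable for fixed input.
    """
    if not restraints:
        raise ValidationError("refusing to write an empty restraint list")
    if dialect == "tsv":
        lines = ["atom_i\tatom_j\tlow_nm\tup_nm\tk_kj_mol_nm2\tprovenance"]
        for r in restraints:
            lines.append(
                f"{r.atom_i}\t{r.atom_j}\t{r.low:.9g}\t{r.up:.9g}"
                f"\t{r.k:.9g}\t{r.provenance}"
            )
        return "\n".join(lines) + "\n"
    if dialect == "gromacs-itp-like":
        index: dict[str, int] = {}
        for r in restraints:
            for label in (r.atom_i, r.atom_j):
                index.setdefault(label, len(index) + 1)
        lines = ["; atom index map (placeholder indices -> labels)"]
        lines += [f"; {idx:>4d} = {label}" for label, idx in index.items()]
        lines.append("[ distance_restraints ]")
        lines.append(";  ai   aj funct index type      low      up1      up2  fac")
        for i, r in enumerate(restraints):
            lines.append(
                f"{index[r.atom_i]:>5d}{index[r.atom_j]:>5d}{1:>6d}"
                f"{i:>6d}{1:>5d}{r.low:>9.3f}{r.up:>9.3f}{r.up + 0.1:>9.3f}"
                f"{r.k / DEFAULT_FORCE_CONSTANT:>5.1f}"
            )
        return "\n".join(lines) + "\n"
    raise ValidationError(f"unknown restraint dialect {dialect!r}")
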