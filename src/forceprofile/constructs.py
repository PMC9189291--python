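"""Arrest-peptide force-sensor constructs and their length bookkeeping.

A force-sensor construct tethers an N-terminal prefix of the domain of
interest to a translational arrest peptide (AP) through an unstructured
linker.  The assay's coordinate is ``L``, the number of residues from the
N-terminal end of the domain part to the last residue of the AP:

    L = domain_length + linker_length + ap.length

The ribosome stalls with the AP's final proline in the peptidyl transferase
center (PTC), so the domain C-terminus sits ``linker_length + ap.length``
residues away from the PTC.  Read-through of the stall appends a 23-residue
C-terminal tail, which is what separates the full-length and arrested chains
on an SDS gel.

Conventions used throughout:

* ``linker_length`` counts *all* residues between the domain C-terminus and
  the AP N-terminus, including the short insulating tetrapeptide; this is
  the only accounting under which the published L values are reproduced by
  plain addition.
* The upstream GSGS insulator and the optional 154-residue unstructured
  N-terminal visualization segment (present for short constructs, L <= 110)
  contribute to chain masses but not to L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import islice, cycle
from typing import Sequence

import numpy as np

__all__ = [
    "SECM_AP_SEQUENCE",
    "AMINO_ACIDS",
    "DEFAULT_REPEAT_BOUNDARIES",
    "ArrestPeptide",
    "ConstructSpec",
    "Construct",
    "RepeatSpan",
    "RepeatAlignment",
    "LogoResult",
    "build_construct",
    "distance_to_ptc",
    "make_controls",
    "generate_library",
    "repeats_spanned",
    "logo_information",
    "placeholder_sequence",
]

#: E. coli SecM arrest peptide; stalling requires the final proline.
SECM_AP_SEQUENCE = "FSTPVWISQHAPIRGSP"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")

UPSTREAM_INSULATOR = "GSGS"
DOWNSTREAM_INSULATOR = "SGSG"

#: Residue offsets delimiting the seven ankyrin repeats of the 239-residue
#: Notch domain: repeat 1 carries a 15-residue insertion (33 + 15 = 48),
#: repeats 2-6 are the canonical 33-residue motif, and the last repeat is
#: trimmed to the domain's C-terminus.  An approximation, overridable.
DEFAULT_REPEAT_BOUNDARIES = (0, 48, 81, 114, 147, 180, 213, 239)

#: Constructs short enough that gel visualization needs an N-terminal
#: extension (L at or below this bound carry the 154-residue segment).
N_TERM_VISUALIZATION_MAX_L = 110

CONTROL_KINDS = ("active", "full_length_control", "arrest_control")


def placeholder_sequence(length: int, pattern: str = "GSS") -> str:
    """Deterministic unstructured filler sequence of the given length.

    Segment identities (LepB-derived linkers, tails) are not part of the
    model — only lengths enter any computation — so placeholders just cycle
    a small Gly/Ser pattern.
    """
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    return "".join(islice(cycle(pattern), length))


@dataclass(frozen=True)
class ArrestPeptide:
    """A translational arrest peptide; active only with a C-terminal proline."""

    sequence: str = SECM_AP_SEQUENCE

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("arrest peptide sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_active(self) -> bool:
        return self.sequence.endswith("P")

    def proline_to_ala(self) -> "ArrestPeptide":
        """Inactivated variant: terminal proline mutated to alanine."""
        if not self.is_active:
            raise ValueError("arrest peptide does not end in proline")
        return ArrestPeptide(self.sequence[:-1] + "A")


@dataclass(frozen=True)
class ConstructSpec:
    """Recipe for one force-sensor construct (lengths, not sequences)."""

    name: str
    domain_length: int
    linker_length: int
    ap: ArrestPeptide = field(default_factory=ArrestPeptide)
    control_kind: str = "active"
    c_tail_length: int = 23
    n_term_length: int = 154

    def __post_init__(self) -> None:
        if self.domain_length < 0:
            raise ValueError(f"domain_length must be >= 0, got {self.domain_length}")
        if self.linker_length < 0:
            raise ValueError(f"linker_length must be >= 0, got {self.linker_length}")
        if self.control_kind not in CONTROL_KINDS:
            raise ValueError(
                f"control_kind must be one of {CONTROL_KINDS}, got {self.control_kind!r}"
            )

    @property
    def L(self) -> int:
        return self.domain_length + self.linker_length + self.ap.length

    @property
    def distance_to_ptc(self) -> int:
        return self.linker_length + self.ap.length

    @property
    def n_term_visualization(self) -> bool:
        return self.L <= N_TERM_VISUALIZATION_MAX_L


@dataclass(frozen=True)
class Construct:
    """A fully assembled construct with both chain sequences.

    ``arrested_sequence`` is the chain produced when the stall holds;
    ``full_sequence`` additionally carries the C-terminal tail whose extra
    mass separates the two species on a gel.
    """

    spec: ConstructSpec
    arrested_sequence: str
    full_sequence: str

    @property
    def L(self) -> int:
        return self.spec.L

    @property
    def arrested_length(self) -> int:
        return len(self.arrested_sequence)

    @property
    def full_length(self) -> int:
        return len(self.full_sequence)

    @property
    def distance_to_ptc(self) -> int:
        return self.spec.distance_to_ptc

    @property
    def name(self) -> str:
        return self.spec.name


def build_construct(
    spec: ConstructSpec,
    domain_sequence: str | None = None,
    *,
    linker_sequence: str | None = None,
    n_term_sequence: str | None = None,
    c_tail_sequence: str | None = None,
) -> Construct:
    """Assemble the arrested and full-length chains for a construct spec.

    Chain layout (N to C):
    ``[n_term?][GSGS][domain prefix][linker (incl. SGSG insulator)][AP][tail]``
    where the tail is present only on the full-length chain and the
    N-terminal segment only when the construct is short (L <= 110).

    ``domain_sequence`` may be omitted, in which case a deterministic
    placeholder is used — lengths, not identities, drive every downstream
    computation.
    """
    if domain_sequence is None:
        domain_sequence = placeholder_sequence(spec.domain_length, "ANK")
    if spec.domain_length > len(domain_sequence):
        raise ValueError(
            f"domain_length {spec.domain_length} exceeds domain sequence "
            f"length {len(domain_sequence)}"
        )
    domain = domain_sequence[: spec.domain_length]

    if linker_sequence is None:
        if spec.linker_length >= len(DOWNSTREAM_INSULATOR):
            linker = (
                placeholder_sequence(spec.linker_length - len(DOWNSTREAM_INSULATOR))
                + DOWNSTREAM_INSULATOR
            )
        else:
            linker = placeholder_sequence(spec.linker_length)
    else:
        linker = linker_sequence
    if len(linker) != spec.linker_length:
        raise ValueError(
            f"linker sequence length {len(linker)} != linker_length {spec.linker_length}"
        )

    if n_term_sequence is None:
        n_term_sequence = placeholder_sequence(spec.n_term_length, "SEG")
    if c_tail_sequence is None:
        c_tail_sequence = placeholder_sequence(spec.c_tail_length, "TGS")

    prefix = ""
    if spec.n_term_visualization:
        prefix = n_term_sequence[: spec.n_term_length]
    arrested = prefix + UPSTREAM_INSULATOR + domain + linker + spec.ap.sequence

    if spec.control_kind == "arrest_control":
        full = arrested  # translation ends at the AP; no tail is ever made
    else:
        full = arrested + c_tail_sequence[: spec.c_tail_length]
    return Construct(spec=spec, arrested_sequence=arrested, full_sequence=full)


def distance_to_ptc(construct: Construct | ConstructSpec) -> int:
    """Residues from the domain C-terminus to the PTC (linker + AP)."""
    return construct.distance_to_ptc


def make_controls(spec: ConstructSpec) -> tuple[ConstructSpec, ConstructSpec]:
    """Band-identity controls for an active construct.

    The full-length control carries an inactivated AP (terminal proline to
    alanine) and always reads through; the arrest control replaces the
    proline codon with a stop, so only the arrested chain is made and the
    23-residue tail never appears.  Neither control changes L.
    """
    if spec.control_kind != "active":
        raise ValueError(
            f"controls are derived from active constructs, got {spec.control_kind!r}"
        )
    fl_control = replace(
        spec,
        name=spec.name + "-Fc",
        ap=spec.ap.proline_to_ala(),
        control_kind="full_length_control",
    )
    arrest_control = replace(
        spec,
        name=spec.name + "-Ac",
        control_kind="arrest_control",
        c_tail_length=0,
    )
    return fl_control, arrest_control


def generate_library(
    domain_length: int = 239,
    linker_start: int = 39,
    linker_min: int = 8,
    linker_step: int = 5,
    trunc_step: int = 5,
    L_min: int = 30,
    ap: ArrestPeptide | None = None,
) -> list[ConstructSpec]:
    """Two-stage truncation library spanning the force profile.

    Stage 1 shortens the linker from ``linker_start`` toward ``linker_min``
    in ``linker_step`` decrements (``linker_min`` always included) at the
    full domain length; stage 2 truncates the domain C-terminus in
    ``trunc_step`` decrements at the fixed minimal linker until L would drop
    below ``L_min``.  The result is sorted by decreasing L with no duplicate
    L values.
    """
    for label, v in (
        ("linker_step", linker_step),
        ("trunc_step", trunc_step),
        ("L_min", L_min),
        ("linker_start", linker_start),
    ):
        if v <= 0:
            raise ValueError(f"{label} must be positive, got {v}")
    if linker_min < 0 or linker_min > linker_start:
        raise ValueError("require 0 <= linker_min <= linker_start")
    if ap is None:
        ap = ArrestPeptide()

    linkers = list(range(linker_start, linker_min - 1, -linker_step))
    if linkers[-1] != linker_min:
        linkers.append(linker_min)

    specs: list[ConstructSpec] = []
    seen_L: set[int] = set()

    def add(dom: int, link: int) -> None:
        L = dom + link + ap.length
        if L < L_min or L in seen_L:
            return
        seen_L.add(L)
        specs.append(
            ConstructSpec(name=f"L{L}", domain_length=dom, linker_length=link, ap=ap)
        )

    for link in linkers:
        add(domain_length, link)
    dom = domain_length - trunc_step
    while dom >= 0 and dom + linker_min + ap.length >= L_min:
        add(dom, linker_min)
        dom -= trunc_step

    if not specs:
        raise ValueError("library parameters produce an empty library")
    specs.sort(key=lambda s: -s.L)
    return specs


@dataclass(frozen=True)
class RepeatSpan:
    """How many complete repeats a domain prefix covers, plus the leftover tail."""

    n_full_repeats: int
    tail_length: int

    def __post_init__(self) -> None:
        if self.n_full_repeats < 0 or self.tail_length < 0:
            raise ValueError("repeat span components must be non-negative")


def repeats_spanned(
    domain_length: int,
    repeat_boundaries: Sequence[int] = DEFAULT_REPEAT_BOUNDARIES,
) -> RepeatSpan:
    """Count complete repeats contained in the first ``domain_length`` residues.

    ``repeat_boundaries`` are cumulative offsets starting at 0 and ending at
    the full domain length; interval i spans boundaries[i]..boundaries[i+1].
    """
    b = list(repeat_boundaries)
    if len(b) < 2 or b[0] != 0:
        raise ValueError("boundaries must start at 0 and delimit >= 1 repeat")
    if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
        raise ValueError("boundaries must be strictly increasing")
    if domain_length < 0 or domain_length > b[-1]:
        raise ValueError(
            f"domain_length {domain_length} outside [0, {b[-1]}] covered by boundaries"
        )
    n_full = sum(1 for i in range(len(b) - 1) if b[i + 1] <= domain_length)
    return RepeatSpan(n_full_repeats=n_full, tail_length=domain_length - b[n_full])


@dataclass(frozen=True)
class RepeatAlignment:
    """Gapped alignment of the repeats of a repeat protein (equal-length rows)."""

    rows: tuple[str, ...]

    def __init__(self, rows: Sequence[str]):
        rows = tuple(r.upper() for r in rows)
        if not rows:
            raise ValueError("alignment must contain at least one row")
        n = len(rows[0])
        if any(len(r) != n for r in rows):
            raise ValueError("all alignment rows must have equal length")
        allowed = set(AMINO_ACIDS) | GAP_CHARS
        for r in rows:
            bad = set(r) - allowed
            if bad:
                raise ValueError(f"invalid alignment characters: {sorted(bad)}")
        object.__setattr__(self, "rows", rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class LogoResult:
    """Per-column residue frequencies and information content of an alignment.

    ``information`` is log2(20) minus the Shannon entropy of the column's
    residue frequencies, in bits; columns consisting only of gaps have no
    defined information and are flagged in ``all_gap`` (information NaN).
    """

    frequencies: np.ndarray  # (n_columns, 20), rows sum to 1 where defined
    information: np.ndarray  # (n_columns,) bits
    all_gap: np.ndarray  # (n_columns,) bool
    alphabet: str = AMINO_ACIDS


def logo_information(
    alignment: RepeatAlignment,
    pseudocount: float = 0.0,
    small_sample_correction: bool = False,
) -> LogoResult:
    """Sequence-logo statistics: per-column frequencies and bits of information.

    Gaps are excluded from the counts.  With ``small_sample_correction`` the
    standard correction e_n = 19 / (2 ln2 n) is subtracted (clamped at 0),
    where n is the number of non-gap residues in the column.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    n_aa = len(AMINO_ACIDS)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((alignment.n_columns, n_aa))
    for row in alignment.rows:
        for j, ch in enumerate(row):
            if ch not in GAP_CHARS:
                counts[j, index[ch]] += 1

    n_obs = counts.sum(axis=1)
    all_gap = n_obs == 0
    counts = counts + pseudocount
    totals = counts.sum(axis=1)

    freqs = np.full_like(counts, np.nan)
    info = np.full(alignment.n_columns, np.nan)
    max_bits = math.log2(n_aa)
    for j in range(alignment.n_columns):
        if all_gap[j] and pseudocount == 0:
            continue
        p = counts[j] / totals[j]
        freqs[j] = p
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        bits = max_bits - entropy
        if small_sample_correction and n_obs[j] > 0:
            bits -= (n_aa - 1) / (2 * math.log(2) * n_obs[j])
        info[j] = max(bits, 0.0)
    return LogoResult(frequencies=freqs, information=info, all_gap=all_gap)
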