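"""Coarse-grained β-strand–turn–β-strand energy scoring of residue windows.

The amyloidogenic propensity of a residue is scored on the ``2j+1`` window
centered on it by threading the window onto a two-strand motif: two
``strand_len``-residue β-strands (A and B) joined by a flexible linker of
0..``max_linker`` residues, in either parallel or antiparallel registration.
Every placement of the motif inside the window is enumerated and scored as

    total = E_inter + E_intra + E_desol

where

* ``E_inter`` — stacking energy against the adjacent, identical chain of the
  fibril: the in-register self-contact ``e(r, r)`` summed over the 12 strand
  residues;
* ``E_intra`` — cross-strand contact energy between strands A and B within
  one chain, summed over a facing + diagonal contact set (11 terms for
  6-residue strands);
* ``E_desol`` — desolvation penalty for burying side chains at the
  sheet–sheet interface, summed over the residues selected by the buried
  rule (default: all strand residues).

The minimum total over all placements is assigned to the window, and the
window is called amyloidogenic when that minimum is strictly below the
classification cutoff (default −54.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence_io import AA_CODE, ALPHABET, AMINO_ACIDS, ProteinRecord, UNKNOWN

__all__ = [
    "DESOLVATION_PENALTIES",
    "EnergyConfig",
    "MotifPlacement",
    "EnergyBreakdown",
    "default_energy_config",
    "load_contact_matrix",
    "contact_energy",
    "desolvation_penalty",
    "enumerate_placements",
    "placement_energy",
    "window_energy",
    "classify_energy",
    "energy_profile",
    "window_energy_profile",
    "write_profile_tsv",
    "summarize_profiles",
]

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"
ORIENTATIONS = (PARALLEL, ANTIPARALLEL)

#: Desolvation penalty for burying each residue at the sheet-sheet interface.
#: These 20 constants are fixed package data; re-optimizing them is out of scope.
DESOLVATION_PENALTIES: dict[str, float] = {
    "G": 0.0, "A": 30.0, "V": -16.0, "I": 9.0, "L": 33.0,
    "S": 8.0, "T": -3.0, "D": 50.0, "N": 44.0, "E": 44.0,
    "Q": 36.0, "K": 50.0, "R": 50.0, "C": 50.0, "M": 34.0,
    "F": -5.0, "Y": 6.0, "W": 20.0, "H": 20.0, "P": 0.0,
}

_DATA_PKG = "amylostretch.data"
_DEFAULT_CONTACT_FILE = "contact_energies_synthetic.tsv"


def load_contact_matrix(path: str | Path | None = None) -> np.ndarray:
    """Load a 20x20 symmetric contact-energy table in :data:`AMINO_ACIDS` order.

    ``path`` may point at a whitespace-delimited matrix with a header row of
    one-letter codes; rows may be full (20 values) or lower-triangular
    (``i+1`` values on row ``i``), which is mirrored. Without ``path`` the
    packaged synthetic surrogate table is loaded (see the file header for its
    construction; it stands in for an unshipped published potential).
    """
    if path is None:
        text = resources.files(_DATA_PKG).joinpath(_DEFAULT_CONTACT_FILE).read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    if sorted(header) != sorted(AMINO_ACIDS):
        raise ValueError("contact matrix header must list the 20 one-letter codes")
    mat = np.full((20, 20), np.nan)
    order = [AMINO_ACIDS.index(a) for a in header]
    if len(lines) != 21:
        raise ValueError(f"expected 20 matrix rows, got {len(lines) - 1}")
    for ri, line in enumerate(lines[1:]):
        parts = line.split()
        row_aa, vals = parts[0], [float(v) for v in parts[1:]]
        i = AMINO_ACIDS.index(row_aa)
        if len(vals) in (20, ri + 1):  # full row, or lower triangle in header order
            for ci, v in enumerate(vals):
                j = order[ci]
                mat[i, j] = v
                if np.isnan(mat[j, i]):
                    mat[j, i] = v
        else:
            raise ValueError(f"row {row_aa!r}: expected 20 or {ri + 1} values")
    if np.isnan(mat).any():
        raise ValueError("contact matrix has missing entries")
    if not np.allclose(mat, mat.T):
        raise ValueError("contact matrix must be symmetric")
    return mat


def _extend_contact(mat20: np.ndarray) -> np.ndarray:
    """Extend a 20x20 table with an 'X' row/column holding column means."""
    ext = np.zeros((21, 21))
    ext[:20, :20] = mat20
    col_mean = mat20.mean(axis=0)
    ext[20, :20] = col_mean
    ext[:20, 20] = col_mean
    ext[20, 20] = col_mean.mean()
    return ext


@dataclass(frozen=True, eq=False)
class EnergyConfig:
    """Parameters of the motif energy engine.

    ``contact_table`` is the raw (unscaled) 20x20 symmetric table in
    :data:`AMINO_ACIDS` order; every contact term is multiplied by
    ``contact_scale``, the calibration knob that puts contact energies on the
    same scale as the desolvation penalties and the cutoff. ``buried_rule``
    selects which residues pay desolvation: ``"all_strand"`` (all residues of
    both strands) or ``"alternating"`` (the inward-facing residues at odd
    strand positions 1, 3, 5, ...).
    """

    contact_table: np.ndarray
    contact_scale: float = 10.0
    desolvation_table: dict[str, float] = field(
        default_factory=lambda: dict(DESOLVATION_PENALTIES)
    )
    cutoff: float = -54.0
    strand_len: int = 6
    max_linker: int = 15
    buried_rule: str = "all_strand"

    def __post_init__(self) -> None:
        mat = np.asarray(self.contact_table, dtype=float)
        if mat.shape != (20, 20):
            raise ValueError("contact_table must be 20x20")
        if not np.allclose(mat, mat.T):
            raise ValueError("contact_table must be symmetric")
        if self.contact_scale <= 0:
            raise ValueError("contact_scale must be positive")
        if set(self.desolvation_table) != set(AMINO_ACIDS):
            raise ValueError("desolvation_table must cover exactly the 20 amino acids")
        if self.strand_len < 1 or self.max_linker < 0:
            raise ValueError("strand_len >= 1 and max_linker >= 0 required")
        if self.buried_rule not in ("all_strand", "alternating"):
            raise ValueError(f"unknown buried_rule {self.buried_rule!r}")
        object.__setattr__(self, "contact_table", mat)
        # cached 21-symbol arrays ('X' = mean over the 20 canonical symbols)
        object.__setattr__(
            self, "_contact21", _extend_contact(mat) * self.contact_scale
        )
        desol = np.array([self.desolvation_table[a] for a in AMINO_ACIDS])
        object.__setattr__(
            self, "_desol21", np.append(desol, desol.mean())
        )

    # -- per-strand index helpers -------------------------------------------------

    def intra_pairs(self, orientation: str) -> list[tuple[int, int]]:
        """Cross-strand contact set as 1-based (strand A, strand B) positions.

        Facing pairs plus one diagonal per facing pair: ``2*strand_len - 1``
        terms (11 for the default 6-residue strands).
        """
        m = self.strand_len
        if orientation == PARALLEL:
            return [(i, i) for i in range(1, m + 1)] + [
                (i, i + 1) for i in range(1, m)
            ]
        if orientation == ANTIPARALLEL:
            return [(i, m + 1 - i) for i in range(1, m + 1)] + [
                (i, m - i) for i in range(1, m)
            ]
        raise ValueError(f"unknown orientation {orientation!r}")

    def buried_strand_offsets(self) -> list[int]:
        """0-based offsets within a strand whose residues pay desolvation."""
        if self.buried_rule == "all_strand":
            return list(range(self.strand_len))
        return list(range(0, self.strand_len, 2))


def default_energy_config(
    contact_path: str | Path | None = None, **overrides
) -> EnergyConfig:
    """Build the default :class:`EnergyConfig`, optionally overriding fields."""
    cfg = EnergyConfig(contact_table=load_contact_matrix(contact_path))
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class MotifPlacement:
    """One candidate strand-turn-strand geometry inside a window.

    ``strand_a_start`` is 1-based within the window; strand A occupies
    ``[start, start+strand_len-1]`` and strand B follows after
    ``linker_len`` turn residues.
    """

    strand_a_start: int
    linker_len: int
    orientation: str


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy terms of (the best placement of) one window."""

    e_inter: float
    e_intra: float
    e_desol: float
    total: float
    placement: MotifPlacement | None = None


#: Returned when no motif placement fits in the window.
SENTINEL = EnergyBreakdown(math.inf, math.inf, math.inf, math.inf, None)


def _code(symbol: str) -> int:
    try:
        return AA_CODE[symbol]
    except KeyError:
        raise ValueError(f"symbol {symbol!r} outside alphabet {ALPHABET!r}") from None


def contact_energy(a: str, b: str, config: EnergyConfig) -> float:
    """Scaled contact energy between two symbols; 'X' rows are 20-symbol means."""
    return float(config._contact21[_code(a), _code(b)])


def desolvation_penalty(a: str, config: EnergyConfig) -> float:
    """Desolvation penalty of one symbol; 'X' maps to the 20-value mean."""
    return float(config._desol21[_code(a)])


def enumerate_placements(window_len: int, config: EnergyConfig) -> list[MotifPlacement]:
    """All motif placements fitting a window, in deterministic order.

    Order: linker length ascending, strand-A start ascending, parallel before
    antiparallel. A window shorter than ``2*strand_len`` yields no placements.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    m = config.strand_len
    out = []
    for linker in range(config.max_linker + 1):
        span = 2 * m + linker
        for start in range(1, window_len - span + 2):
            for orientation in ORIENTATIONS:
                out.append(MotifPlacement(start, linker, orientation))
    return out


def _strand_codes(segment: str, p: MotifPlacement, config: EnergyConfig):
    m = config.strand_len
    s0 = p.strand_a_start - 1
    b0 = s0 + m + p.linker_len
    if s0 < 0 or b0 + m > len(segment):
        raise ValueError(f"placement {p} does not fit window of length {len(segment)}")
    a = np.array([_code(c) for c in segment[s0 : s0 + m]])
    b = np.array([_code(c) for c in segment[b0 : b0 + m]])
    return a, b


def placement_energy(
    segment: str, p: MotifPlacement, config: EnergyConfig
) -> EnergyBreakdown:
    """Score one placement of the motif on a window segment."""
    a, b = _strand_codes(segment, p, config)
    tab = config._contact21
    diag = tab.diagonal()
    e_inter = float(diag[a].sum() + diag[b].sum())
    e_intra = float(
        sum(tab[a[i - 1], b[k - 1]] for i, k in config.intra_pairs(p.orientation))
    )
    buried = config.buried_strand_offsets()
    desol = config._desol21
    e_desol = float(desol[a[buried]].sum() + desol[b[buried]].sum())
    return EnergyBreakdown(e_inter, e_intra, e_desol, e_inter + e_intra + e_desol, p)


def window_energy(segment: str, config: EnergyConfig) -> EnergyBreakdown:
    """Minimum placement energy of a window (exhaustive search).

    Ties are broken by enumeration order. If no placement fits, a sentinel
    breakdown with ``total = +inf`` and no placement is returned.
    """
    best = SENTINEL
    for p in enumerate_placements(len(segment), config):
        e = placement_energy(segment, p, config)
        if e.total < best.total:
            best = e
    return best


def classify_energy(e: EnergyBreakdown, config: EnergyConfig) -> int:
    """1 iff the total is strictly below the cutoff (sentinel windows are 0)."""
    return int(math.isfinite(e.total) and e.total < config.cutoff)


def window_energy_profile(
    sequence: str, flank_j: int, config: EnergyConfig
) -> list[EnergyBreakdown]:
    """Vectorized :func:`window_energy` over every centered window of a sequence.

    Equivalent to scoring ``extract_windows`` output one by one (terminal
    windows are 'X'-padded), but evaluates all placements for all centers with
    array gathers. Returns one breakdown per residue.
    """
    n = len(sequence)
    width = 2 * flank_j + 1
    placements = enumerate_placements(width, config)
    if not placements:
        return [SENTINEL] * n
    codes = np.array([_code(c) for c in sequence])
    padded = np.concatenate(
        [np.full(flank_j, AA_CODE[UNKNOWN]), codes, np.full(flank_j, AA_CODE[UNKNOWN])]
    )
    base = np.arange(n)[:, None]  # window for center c spans padded[c : c+width]
    tab = config._contact21
    diag = tab.diagonal()
    desol = config._desol21
    m = config.strand_len
    buried = np.array(config.buried_strand_offsets())
    P = len(placements)
    e_inter = np.empty((P, n))
    e_intra = np.empty((P, n))
    e_desol = np.empty((P, n))
    for pi, p in enumerate(placements):
        s0 = p.strand_a_start - 1
        idx_a = padded[base + (s0 + np.arange(m))]
        idx_b = padded[base + (s0 + m + p.linker_len + np.arange(m))]
        e_inter[pi] = diag[idx_a].sum(axis=1) + diag[idx_b].sum(axis=1)
        acc = np.zeros(n)
        for i, k in config.intra_pairs(p.orientation):
            acc += tab[idx_a[:, i - 1], idx_b[:, k - 1]]
        e_intra[pi] = acc
        e_desol[pi] = desol[idx_a[:, buried]].sum(axis=1) + desol[idx_b[:, buried]].sum(
            axis=1
        )
    totals = e_inter + e_intra + e_desol
    best = totals.argmin(axis=0)  # first minimum == enumeration-order tie-break
    return [
        EnergyBreakdown(
            float(e_inter[b, c]),
            float(e_intra[b, c]),
            float(e_desol[b, c]),
            float(totals[b, c]),
            placements[b],
        )
        for c, b in enumerate(best)
    ]


def energy_profile(
    record: ProteinRecord, flank_j: int, config: EnergyConfig
) -> list[tuple[EnergyBreakdown, int]]:
    """Per-residue (breakdown, amyloidogenic call) profile of a protein."""
    return [
        (e, classify_energy(e, config))
        for e in window_energy_profile(record.sequence, flank_j, config)
    ]


def write_profile_tsv(
    profiles: dict[str, tuple[ProteinRecord, list[tuple[EnergyBreakdown, int]]]],
    path: str | Path,
) -> Path:
    """Write per-residue profiles as TSV (1-based positions).

    Columns: protein_id, position, residue, e_inter, e_intra, e_desol,
    e_total, call, placement (``start:linker:orientation`` or NA).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tposition\tresidue\te_inter\te_intra\te_desol\te_total"
            "\tcall\tplacement\n"
        )
        for pid, (rec, prof) in profiles.items():
            for pos, (e, call) in enumerate(prof, 1):
                pl = e.placement
                pl_s = (
                    "NA"
                    if pl is None
                    else f"{pl.strand_a_start}:{pl.linker_len}:{pl.orientation}"
                )
                fh.write(
                    f"{pid}\t{pos}\t{rec.sequence[pos - 1]}\t{e.e_inter:.6g}\t"
                    f"{e.e_intra:.6g}\t{e.e_desol:.6g}\t{e.total:.6g}\t{call}\t{pl_s}\n"
                )
    return path


def summarize_profiles(
    profiles: dict[str, tuple[ProteinRecord, list[tuple[EnergyBreakdown, int]]]],
) -> dict[str, float]:
    """Residue- and protein-level amyloidogenic percentages of a scan.

    ``residue_pct`` is the percentage of residues called amyloidogenic;
    ``protein_pct`` the percentage of proteins containing at least one call.
    Both are reported because "percentage of amyloidogenic segments" is
    ambiguous between the two.
    """
    n_res = sum(len(prof) for _, prof in profiles.values())
    n_called = sum(call for _, prof in profiles.values() for _, call in prof)
    n_prot = len(profiles)
    prot_called = sum(
        1 for _, prof in profiles.values() if any(call for _, call in prof)
    )
    return {
        "n_residues": n_res,
        "n_residues_called": n_called,
        "residue_pct": 100.0 * n_called / n_res if n_res else 0.0,
        "n_proteins": n_prot,
        "n_proteins_called": prot_called,
        "protein_pct": 100.0 * prot_called / n_prot if n_prot else 0.0,
    }
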