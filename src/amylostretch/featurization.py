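"""Window feature matrices from pluggable per-residue feature providers.

A labeled residue window of half-width ``j`` is encoded position-major: for
each of the ``2j+1`` window positions, every provider contributes its
per-residue attributes for the residue occupying that position. With the
default 34-attribute schema (20 PSSM + 5 physicochemical + 1 disorder +
3 secondary-structure + 1 solvent-accessibility + 4 conservation) a 27-residue
window yields 918 columns; appending the per-position motif energy adds
another 27.

Padded positions beyond the protein termini take the per-attribute dataset
mean, so every residue of every protein yields a complete row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .motif_energy import EnergyConfig, window_energy_profile
from .sequence_io import AMINO_ACIDS, ProteinRecord, UNKNOWN

logger = logging.getLogger(__name__)

CATEGORIES = (
    "pssm",
    "physicochemical",
    "disorder",
    "secondary_structure",
    "solvent_accessibility",
    "conservation",
    "energy",
)


class ConfigurationError(ValueError):
    """Provider/schema wiring error (shape or coverage mismatch)."""


@dataclass(frozen=True)
class SchemaEntry:
    position: int  # 1-based window position, 1..2j+1
    attribute: str
    category: str


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered mapping column index -> (window position, attribute, category)."""

    entries: tuple[SchemaEntry, ...]
    flank_j: int

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def column_names(self) -> list[str]:
        return [f"{e.position:02d}|{e.category}|{e.attribute}" for e in self.entries]

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.entries])

    @property
    def categories(self) -> list[str]:
        return [e.category for e in self.entries]

    def subset(self, indices: Sequence[int]) -> "FeatureSchema":
        return FeatureSchema(
            tuple(self.entries[i] for i in indices), flank_j=self.flank_j
        )

    @staticmethod
    def from_column_names(names: Sequence[str], flank_j: int) -> "FeatureSchema":
        entries = []
        for name in names:
            pos_s, category, attribute = name.split("|", 2)
            entries.append(SchemaEntry(int(pos_s), attribute, category))
        return FeatureSchema(tuple(entries), flank_j=flank_j)


class FeatureProvider:
    """Interface: a named block of per-residue numeric attributes.

    Subclasses implement :meth:`residue_table`, returning one row per residue
    of the record. Values for 'X'-padded window positions are imputed with the
    per-attribute dataset mean by :func:`build_feature_matrix`.
    """

    name: str
    category: str
    attribute_names: list[str]

    @property
    def width(self) -> int:
        return len(self.attribute_names)

    def residue_table(self, record: ProteinRecord) -> np.ndarray:  # (len, width)
        raise NotImplementedError


class AAIndexProvider(FeatureProvider):
    """Width-1 provider performing a per-residue scale lookup.

    The table must cover the 20 canonical amino acids; 'X' maps to their mean.
    """

    def __init__(self, table: dict[str, float], name: str,
                 category: str = "physicochemical"):
        missing = set(AMINO_ACIDS) - set(table)
        if missing:
            raise ConfigurationError(f"index {name!r} missing symbols {sorted(missing)}")
        self.name = name
        self.category = category
        self.attribute_names = [name]
        self._lut = {a: float(table[a]) for a in AMINO_ACIDS}
        self._lut[UNKNOWN] = float(np.mean(list(self._lut.values())))

    def residue_table(self, record: ProteinRecord) -> np.ndarray:
        return np.array([[self._lut[c]] for c in record.sequence])


def aaindex_provider(table: dict[str, float], name: str,
                     category: str = "physicochemical") -> AAIndexProvider:
    return AAIndexProvider(table, name, category)


def default_physicochemical_providers() -> list[AAIndexProvider]:
    """The five physicochemical scales shipped as package data."""
    text = (
        resources.files("amylostretch.data")
        .joinpath("physicochemical_indices.tsv")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    tables: dict[str, dict[str, float]] = {h: {} for h in header}
    for line in lines[1:]:
        parts = line.split("\t")
        for h, v in zip(header, parts[1:]):
            tables[h][parts[0]] = float(v)
    return [aaindex_provider(tables[h], h) for h in header]


class InMemoryProvider(FeatureProvider):
    """Provider backed by precomputed dense per-protein arrays."""

    def __init__(self, name: str, category: str, attribute_names: list[str],
                 tables: dict[str, np.ndarray]):
        self.name = name
        self.category = category
        self.attribute_names = list(attribute_names)
        self._tables = tables

    def residue_table(self, record: ProteinRecord) -> np.ndarray:
        try:
            tab = self._tables[record.id]
        except KeyError:
            raise ConfigurationError(
                f"provider {self.name!r} has no values for protein {record.id!r}"
            ) from None
        if tab.shape != (len(record), self.width):
            raise ConfigurationError(
                f"provider {self.name!r}: table shape {tab.shape} does not match "
                f"protein {record.id!r} ({len(record)} x {self.width})"
            )
        return tab


class TabularProvider(FeatureProvider):
    """Provider serving externally computed per-residue values from a TSV.

    Expected format: header ``protein_id<TAB>position<TAB><attr1>..<attrK>``,
    then one row per (protein, 1-based position). Missing (protein, position)
    pairs are imputed with the per-attribute means over the file, with a
    warning.
    """

    def __init__(self, path: str | Path, name: str, width: int,
                 category: str = "pssm"):
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 3 or header[0] != "protein_id" or header[1] != "position":
                raise ConfigurationError(
                    f"{path}: header must start with protein_id, position"
                )
            attrs = header[2:]
            if len(attrs) != width:
                raise ConfigurationError(
                    f"{path}: expected width {width}, header has {len(attrs)} columns"
                )
            values: dict[str, dict[int, np.ndarray]] = {}
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(header):
                    raise ValueError(
                        f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                    )
                try:
                    pos = int(parts[1])
                    vec = np.array([float(v) for v in parts[2:]])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
                values.setdefault(parts[0], {})[pos] = vec
        if not values:
            raise ConfigurationError(f"{path}: no data rows")
        self.name = name
        self.category = category
        self.attribute_names = attrs
        self._values = values
        self._col_means = np.mean(
            [v for by_pos in values.values() for v in by_pos.values()], axis=0
        )

    def residue_table(self, record: ProteinRecord) -> np.ndarray:
        by_pos = self._values.get(record.id, {})
        out = np.empty((len(record), self.width))
        n_missing = 0
        for i in range(len(record)):
            vec = by_pos.get(i + 1)
            if vec is None:
                out[i] = self._col_means
                n_missing += 1
            else:
                out[i] = vec
        if n_missing:
            logger.warning(
                "provider %r: %d/%d residues of %r mean-imputed",
                self.name, n_missing, len(record), record.id,
            )
        return out


def load_tabular_provider(path: str | Path, name: str, width: int,
                          category: str = "pssm") -> TabularProvider:
    return TabularProvider(path, name, width, category)


class EnergyTotalProvider(FeatureProvider):
    """Per-residue minimized motif-energy totals as a width-1 provider.

    The value at residue ``i`` is the minimum strand-turn-strand energy of the
    ``2j+1`` window centered on ``i``. Non-finite sentinels (windows too short
    to host the motif) are replaced by 0.
    """

    def __init__(self, config: EnergyConfig, flank_j: int):
        self.name = "energy"
        self.category = "energy"
        self.attribute_names = ["energy"]
        self._config = config
        self._flank_j = flank_j

    def residue_table(self, record: ProteinRecord) -> np.ndarray:
        totals = np.array(
            [e.total for e in window_energy_profile(
                record.sequence, self._flank_j, self._config)]
        )
        totals[~np.isfinite(totals)] = 0.0
        return totals[:, None]


@dataclass
class FeatureMatrix:
    """Samples x features table with labels and a column schema.

    One row per residue window; ``sample_ids`` holds the (protein_id, center)
    pair of each row, center 1-based.
    """

    values: np.ndarray
    schema: FeatureSchema
    labels: np.ndarray
    sample_ids: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.values.shape
        if not (n == len(self.labels) == len(self.sample_ids)):
            raise ValueError("row / label / sample_id counts disagree")
        if d != len(self.schema):
            raise ValueError(
                f"{d} columns but schema has {len(self.schema)} entries"
            )
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            self.values[:, idx], self.schema.subset(idx), self.labels,
            list(self.sample_ids),
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.values, columns=self.schema.column_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "center", [c for _, c in self.sample_ids])
        df.insert(0, "protein_id", [p for p, _ in self.sample_ids])
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path

    @staticmethod
    def from_tsv(path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = ["protein_id", "center", "label"]
        feat_cols = [c for c in df.columns if c not in meta]
        positions = [int(c.split("|", 1)[0]) for c in feat_cols]
        flank_j = (max(positions) - 1) // 2 if positions else 0
        return FeatureMatrix(
            values=df[feat_cols].to_numpy(float),
            schema=FeatureSchema.from_column_names(feat_cols, flank_j=flank_j),
            labels=df["label"].to_numpy(int),
            sample_ids=list(zip(df["protein_id"], df["center"].astype(int))),
        )


def _stacked_tables(
    records: Sequence[ProteinRecord], providers: Sequence[FeatureProvider]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-protein residue tables (providers hstacked) and dataset column means."""
    tables = {}
    for rec in records:
        blocks = []
        for prov in providers:
            tab = np.asarray(prov.residue_table(rec), dtype=float)
            if tab.shape != (len(rec), prov.width):
                raise ConfigurationError(
                    f"provider {prov.name!r} returned shape {tab.shape} for "
                    f"{rec.id!r}, expected ({len(rec)}, {prov.width})"
                )
            blocks.append(tab)
        tables[rec.id] = np.hstack(blocks)
    means = np.vstack(list(tables.values())).mean(axis=0)
    return tables, means


def _window_rows(table: np.ndarray, means: np.ndarray, flank_j: int) -> np.ndarray:
    """Expand a (L, W) residue table into (L, (2j+1)*W) window rows."""
    L, W = table.shape
    pad = np.tile(means, (flank_j, 1))
    padded = np.vstack([pad, table, pad])
    out = np.empty((L, (2 * flank_j + 1) * W))
    for p in range(2 * flank_j + 1):
        out[:, p * W : (p + 1) * W] = padded[p : p + L]
    return out


def build_feature_matrix(
    records: Sequence[ProteinRecord],
    flank_j: int,
    providers: Sequence[FeatureProvider],
) -> FeatureMatrix:
    """One row per residue window across all records, columns position-major.

    All records must carry labels. Column order is a pure function of
    ``(flank_j, providers)``: position 1..2j+1, then provider order, then the
    provider's attribute order.
    """
    if flank_j < 0:
        raise ValueError("flank_j must be >= 0")
    unlabeled = [r.id for r in records if r.labels is None]
    if unlabeled:
        raise ValueError(f"records without labels: {unlabeled}")
    entries = [
        SchemaEntry(p, attr, prov.category)
        for p in range(1, 2 * flank_j + 2)
        for prov in providers
        for attr in prov.attribute_names
    ]
    tables, means = _stacked_tables(records, providers)
    rows = np.vstack([_window_rows(tables[r.id], means, flank_j) for r in records])
    labels = np.concatenate([np.array(r.labels) for r in records])
    sample_ids = [(r.id, i + 1) for r in records for i in range(len(r))]
    return FeatureMatrix(rows, FeatureSchema(tuple(entries), flank_j), labels,
                         sample_ids)


def append_energy_features(
    m: FeatureMatrix, records: Sequence[ProteinRecord], config: EnergyConfig
) -> FeatureMatrix:
    """Append one minimized motif-energy column per window position.

    The energy attribute at window position ``p`` of a sample is the window
    energy of the ``2j+1`` window centered on the residue occupying ``p``
    (computed on the source protein); padded positions take the dataset mean,
    like any other provider.
    """
    by_id = {r.id: r for r in records}
    missing = {pid for pid, _ in m.sample_ids} - set(by_id)
    if missing:
        raise ConfigurationError(f"records missing for proteins: {sorted(missing)}")
    flank_j = m.schema.flank_j
    prov = EnergyTotalProvider(config, flank_j)
    used = [by_id[pid] for pid in dict.fromkeys(pid for pid, _ in m.sample_ids)]
    tables, means = _stacked_tables(used, [prov])
    blocks = {r.id: _window_rows(tables[r.id], means, flank_j) for r in used}
    energy_rows = np.empty((m.n_samples, 2 * flank_j + 1))
    for i, (pid, center) in enumerate(m.sample_ids):
        energy_rows[i] = blocks[pid][center - 1]
    entries = m.schema.entries + tuple(
        SchemaEntry(p, "energy", "energy") for p in range(1, 2 * flank_j + 2)
    )
    return FeatureMatrix(
        np.hstack([m.values, energy_rows]),
        FeatureSchema(entries, flank_j),
        m.labels,
        list(m.sample_ids),
    )


def zscore_columns(m: FeatureMatrix) -> FeatureMatrix:
    """Optional column standardization (constant columns left at zero)."""
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0)
    sd[sd == 0] = 1.0
    return FeatureMatrix((m.values - mu) / sd, m.schema, m.labels,
                         list(m.sample_ids))
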