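"""Readers and writers for every external artifact the pipeline touches.

Formats
-------
* Prediction table: tab-separated, UTF-8, header
  ``protein_id  position  model_id  p_A ... p_Y`` (20 ``p_`` columns in
  canonical alphabet order), positions 1-based.
* Labels table: ``protein_id  position  wt_aa  rsa  aa_class``.
* FASTA (standard), parsed with Biopython.
* RCSB-style cluster list: one cluster of whitespace-separated entity ids
  per non-blank line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from predstack.alphabet import CANONICAL_AA, N_AA, SEQUENCE_LETTERS
from predstack.errors import (
    ConsistencyError,
    DuplicateRecordError,
    FormatError,
    TableValueError,
)

logger = logging.getLogger(__name__)

#: Column names of the prediction-table dialect, in order.
PREDICTION_COLUMNS: tuple[str, ...] = (
    "protein_id",
    "position",
    "model_id",
    *(f"p_{aa}" for aa in CANONICAL_AA),
)

LABEL_COLUMNS: tuple[str, ...] = ("protein_id", "position", "wt_aa", "rsa", "aa_class")

#: Row probability sums outside [1 - SUM_TOLERANCE, 1 + SUM_TOLERANCE] are
#: rejected; inside, the vector is renormalized to sum exactly 1.
SUM_TOLERANCE = 1e-3


@dataclass
class SiteRecord:
    """One residue site.

    position is a 1-based index into the protein sequence; rsa, when
    present, is unclipped relative solvent accessibility (values slightly
    above 1 are possible and preserved).
    """

    protein_id: str
    position: int
    wt_aa: str
    rsa: float | None = None
    aa_class: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise TableValueError(
                f"site position must be >= 1, got {self.position} "
                f"({self.protein_id})"
            )


@dataclass
class PredictionSet:
    """Per (protein, site, model) 20-way probability vectors.

    entries maps (protein_id, position, model_id) to a length-20 vector in
    canonical alphabet order; model_ids preserves model order.
    """

    model_ids: list[str] = field(default_factory=list)
    entries: dict[tuple[str, int, str], np.ndarray] = field(default_factory=dict)

    def add(self, protein_id: str, position: int, model_id: str, vector: np.ndarray) -> None:
        key = (protein_id, position, model_id)
        if key in self.entries:
            raise DuplicateRecordError(f"duplicate prediction record {key}")
        if model_id not in self.model_ids:
            self.model_ids.append(model_id)
        self.entries[key] = np.asarray(vector, dtype=float)

    def vector(self, protein_id: str, position: int, model_id: str) -> np.ndarray:
        return self.entries[(protein_id, position, model_id)]

    def sites(self) -> list[tuple[str, int]]:
        """Sorted unique (protein_id, position) pairs."""
        return sorted({(pid, pos) for pid, pos, _ in self.entries})

    def protein_ids(self) -> list[str]:
        return sorted({pid for pid, _, _ in self.entries})

    def incomplete_sites(self) -> list[tuple[str, int]]:
        """Sites missing a vector for at least one model in model_ids."""
        out = []
        for pid, pos in self.sites():
            if any((pid, pos, mid) not in self.entries for mid in self.model_ids):
                out.append((pid, pos))
        return out

    def subset(self, protein_ids: Iterable[str]) -> "PredictionSet":
        keep = set(protein_ids)
        sub = PredictionSet(model_ids=list(self.model_ids))
        sub.entries = {k: v for k, v in self.entries.items() if k[0] in keep}
        return sub

    def __len__(self) -> int:
        return len(self.entries)


def read_prediction_table(path: str | Path) -> PredictionSet:
    """Load a tab-separated prediction table.

    Vectors whose sums lie within ``SUM_TOLERANCE`` of 1 are renormalized
    to sum exactly 1; anything further off is rejected with the offending
    1-based data-row number. Duplicate (protein, position, model) rows and
    non-finite or negative probabilities are errors.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "model_id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in PREDICTION_COLUMNS]
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {', '.join(extra)}")

    pset = PredictionSet()
    prob_cols = list(PREDICTION_COLUMNS[3:])
    probs = frame[prob_cols].to_numpy(dtype=float)
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        v = probs[i - 1]
        if not np.all(np.isfinite(v)):
            raise TableValueError(f"{path}: non-finite probability in data row {i}")
        if np.any(v < 0):
            raise TableValueError(f"{path}: negative probability in data row {i}")
        total = float(v.sum())
        if not (1 - SUM_TOLERANCE <= total <= 1 + SUM_TOLERANCE):
            raise TableValueError(
                f"{path}: probabilities in data row {i} sum to {total:.6g}, "
                f"outside [{1 - SUM_TOLERANCE}, {1 + SUM_TOLERANCE}]"
            )
        pset.add(str(row.protein_id), int(row.position), str(row.model_id), v / total)

    incomplete = pset.incomplete_sites()
    if incomplete:
        logger.warning(
            "%s: %d site(s) lack predictions for some models (first: %s)",
            path, len(incomplete), incomplete[0],
        )
    return pset


def write_prediction_table(pset: PredictionSet, path: str | Path) -> None:
    """Write a PredictionSet; round trips preserve probabilities to <=1e-9."""
    path = Path(path)
    order = {mid: k for k, mid in enumerate(pset.model_ids)}
    keys = sorted(pset.entries, key=lambda k: (k[0], k[1], order[k[2]]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for pid, pos, mid in keys:
            v = pset.entries[(pid, pos, mid)]
            cells = [pid, str(pos), mid] + [format(x, ".17g") for x in v]
            fh.write("\t".join(cells) + "\n")


def read_labels_table(path: str | Path) -> list[SiteRecord]:
    """Load a labels table (protein_id, position, wt_aa, rsa, aa_class)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in LABEL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        rsa = None if pd.isna(row.rsa) else float(row.rsa)
        aa_class = None if pd.isna(row.aa_class) else str(row.aa_class)
        records.append(SiteRecord(str(row.protein_id), int(row.position),
                                  str(row.wt_aa), rsa, aa_class))
    return records


def write_labels_table(records: Sequence[SiteRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(LABEL_COLUMNS) + "\n")
        for r in records:
            rsa = "" if r.rsa is None else format(r.rsa, ".12g")
            cls = "" if r.aa_class is None else r.aa_class
            fh.write(f"{r.protein_id}\t{r.position}\t{r.wt_aa}\t{rsa}\t{cls}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {protein_id: uppercase sequence}.

    The id is the first whitespace-delimited token of the header. Letters
    outside the canonical alphabet plus "X" are a format error.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {record.id!r}")
        for j, letter in enumerate(seq, start=1):
            if letter not in SEQUENCE_LETTERS:
                raise FormatError(
                    f"{path}: invalid letter {letter!r} at position {j} of "
                    f"record {record.id!r}"
                )
        if record.id in sequences:
            raise DuplicateRecordError(f"{path}: duplicate record id {record.id!r}")
        sequences[record.id] = seq
    return sequences


def _normalize_entity_id(entity_id: str) -> str:
    """Case-insensitive structure id: prefix before the first underscore."""
    return entity_id.split("_", 1)[0].upper()


@dataclass
class ClusterTable:
    """Homology clusters: each member id belongs to exactly one cluster."""

    clusters: list[list[str]] = field(default_factory=list)
    member_index: dict[str, int] = field(default_factory=dict)
    # normalized structure id -> set of cluster ordinals (one structure may
    # have entities in several clusters)
    _prefix_index: dict[str, set[int]] = field(default_factory=dict)

    def find_clusters(self, any_id: str) -> set[int]:
        """Cluster ordinals matching an exact entity id or a bare PDB id."""
        if any_id in self.member_index:
            return {self.member_index[any_id]}
        return set(self._prefix_index.get(_normalize_entity_id(any_id), set()))


def parse_cluster_file(path: str | Path) -> ClusterTable:
    """Parse a plain-text cluster list (one cluster per non-blank line)."""
    table = ClusterTable()
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            members = line.split()
            if not members:
                continue
            ordinal = len(table.clusters)
            for member in members:
                if member in table.member_index:
                    raise ConsistencyError(
                        f"{path}: id {member!r} appears in more than one cluster"
                    )
                table.member_index[member] = ordinal
                table._prefix_index.setdefault(_normalize_entity_id(member), set()).add(ordinal)
            table.clusters.append(members)
    return table


def filter_training_entries(
    candidates: Sequence[tuple[str, int, bool]],
    excluded_ids: Iterable[str],
    clusters: ClusterTable,
    max_length: int = 1024,
) -> tuple[list[str], dict[str, str]]:
    """Apply the training-set curation filters.

    A candidate (id, length, protonation_ok) is removed iff, checked in this
    order: (a) its id or any member of its cluster is excluded ("homology"),
    (b) length > max_length ("length"), (c) protonation failed
    ("protonation"). Unclustered candidates are retained with a warning.

    Returns (retained ids, {removed id: reason}).
    """
    excluded_clusters: set[int] = set()
    excluded_keys: set[str] = set()
    for ex in excluded_ids:
        excluded_clusters |= clusters.find_clusters(ex)
        excluded_keys.add(_normalize_entity_id(ex))

    retained: list[str] = []
    reasons: dict[str, str] = {}
    for cand_id, length, protonation_ok in candidates:
        cand_clusters = clusters.find_clusters(cand_id)
        if not cand_clusters:
            logger.warning("candidate %s not found in cluster table; retained "
                           "subject to remaining filters", cand_id)
        if _normalize_entity_id(cand_id) in excluded_keys or (cand_clusters & excluded_clusters):
            reasons[cand_id] = "homology"
        elif length > max_length:
            reasons[cand_id] = "length"
        elif not protonation_ok:
            reasons[cand_id] = "protonation"
        else:
            retained.append(cand_id)
    return retained, reasons


def validate_probability_vector(v: np.ndarray, tol: float = 1e-6) -> bool:
    """True iff v is length 20, finite, nonnegative, and sums to 1 +- tol."""
    v = np.asarray(v)
    return (
        v.shape == (N_AA,)
        and bool(np.all(np.isfinite(v)))
        and bool(np.all(v >= 0))
        and math.isclose(float(v.sum()), 1.0, abs_tol=tol)
    )
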