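"""Sequence encoders: AAC, conjoint triad (CTF), chaos game (CGR).

Three frequency encodings of a protein sequence and their concatenations:

* **AAC** — amino-acid composition, the normalized frequency ``f_i = n_i/L``
  of each of the 20 residues, in alphabetical one-letter order (20-d).
* **CTF** — conjoint triad feature.  The sequence is reduced to the
  seven-class alphabet {AGV},{ILFP},{YMTS},{HNQW},{RK},{DE},{C}; a width-3
  window slides over the reduced sequence and each of the 7x7x7 = 343
  ordered triad types is counted, normalized by the number of windows,
  ``f_i = n_i/(L-2)`` (343-d; requires L >= 3).
* **CGR** — chaos game representation on a regular 12-gon.  Vertex k sits
  at ``(cos((k-1)pi/6), sin((k-1)pi/6))``; starting from the centre, each
  residue selects the vertex of its 12-group class and the trajectory moves
  to the midpoint between the current point and that vertex.  The unit disc
  is divided into 24 equal angular sectors and the fraction ``D_k = L_k/N``
  of trajectory points per sector is the feature (24-d).

Seven feature sets are exposed (canonical block order AAC, CGR, CTF):
``aac`` 20, ``cgr`` 24, ``ctf`` 343, ``aac+cgr`` 44, ``aac+ctf`` 363,
``ctf+cgr`` 367, ``aac+cgr+ctf`` 387.

All encoders are scikit-learn transformers operating on lists of residue
strings (or :class:`~nrcascade.seqio.ProteinRecord`); module-level
functions cover single sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabets import CGR12_ALPHABET, CTF_ALPHABET, STANDARD_AA, AlphabetMap
from .errors import ConfigurationError, ConsistencyError, SequenceDomainError
from .seqio import ProteinRecord

__all__ = [
    "FeatureVector",
    "CGRPolygonConfig",
    "FEATURE_SETS",
    "canonical_feature_set",
    "feature_names",
    "compute_aac",
    "reduce_sequence",
    "triad_index",
    "triad_label",
    "compute_ctf",
    "cgr_trajectory",
    "cgr_features",
    "compute_cgr",
    "combine_features",
    "encode_record",
    "AACEncoder",
    "CTFEncoder",
    "CGREncoder",
    "SequenceEncoder",
]

# canonical feature sets: name -> ordered block tuple (AAC, CGR, CTF order)
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "aac": ("aac",),
    "cgr": ("cgr",),
    "ctf": ("ctf",),
    "aac+cgr": ("aac", "cgr"),
    "aac+ctf": ("aac", "ctf"),
    "ctf+cgr": ("cgr", "ctf"),
    "aac+cgr+ctf": ("aac", "cgr", "ctf"),
}

_BLOCK_DIMS = {"aac": 20, "cgr": 24, "ctf": 343}

FEATURE_DIMS = {
    name: sum(_BLOCK_DIMS[b] for b in blocks) for name, blocks in FEATURE_SETS.items()
}

_CANONICAL_BY_BLOCKSET = {frozenset(v): k for k, v in FEATURE_SETS.items()}


def canonical_feature_set(name: str) -> str:
    """Normalize a feature-set name: ``'ctf+aac'`` -> ``'aac+ctf'``."""
    blocks = frozenset(p.strip().lower() for p in name.split("+") if p.strip())
    if not blocks or not blocks <= {"aac", "cgr", "ctf"}:
        raise ConfigurationError(
            f"unknown feature set {name!r}; valid: {sorted(FEATURE_SETS)}"
        )
    return _CANONICAL_BY_BLOCKSET[blocks]


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-dimension encoding of one sequence, tagged by feature set."""

    feature_set: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        expected = FEATURE_DIMS.get(self.feature_set)
        if expected is None:
            raise ConfigurationError(f"unknown feature set {self.feature_set!r}")
        if values.shape != (expected,):
            raise ConsistencyError(
                f"feature set {self.feature_set!r} expects dimension {expected}, "
                f"got shape {values.shape}"
            )

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CGRPolygonConfig:
    """Geometry of the chaos-game 12-gon.

    ``vertex_groups`` must have exactly 12 groups; group k feeds vertex k.
    Vertex k is at ``(cos((k-1)pi/6), sin((k-1)pi/6))`` so vertex 1 is
    (1, 0); the centre (0, 0) is the trajectory origin.  The disc is split
    into ``n_segments`` equal sectors of angle ``pi/12``; a point exactly on
    a boundary ray belongs to the lower-index adjacent sector, with sector 1
    owning the positive x-axis (angle 0).
    """

    vertex_groups: AlphabetMap = CGR12_ALPHABET
    n_segments: int = 24
    vertices: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.vertex_groups.n_groups != 12:
            raise ConfigurationError(
                f"CGR vertex alphabet needs 12 groups, got {self.vertex_groups.n_groups}"
            )
        if self.n_segments != 24:
            raise ConfigurationError("the segment counting scheme uses 24 segments")
        k = np.arange(12)
        verts = np.column_stack((np.cos(k * np.pi / 6), np.sin(k * np.pi / 6)))
        object.__setattr__(self, "vertices", verts)


DEFAULT_CGR_CONFIG = CGRPolygonConfig()

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


def _residues_of(record) -> str:
    if isinstance(record, ProteinRecord):
        return record.residues
    return str(record)


def compute_aac(record) -> FeatureVector:
    """Amino-acid composition: ``f_i = n_i / L`` over the alphabetically
    ordered 20 residues."""
    residues = _residues_of(record)
    if not residues:
        raise SequenceDomainError("AAC undefined for an empty sequence")
    counts = np.zeros(20)
    for r in residues:
        try:
            counts[_AA_INDEX[r]] += 1
        except KeyError:
            raise SequenceDomainError(f"non-standard residue {r!r}") from None
    return FeatureVector("aac", counts / len(residues))


def reduce_sequence(record, alphabet: AlphabetMap = CTF_ALPHABET) -> list[int]:
    """Map each residue to its 1-based class index under ``alphabet``."""
    return alphabet.reduce(_residues_of(record))


def triad_index(c1: int, c2: int, c3: int) -> int:
    """1-based index of an ordered class triad in lexicographic base-7
    order: ``(c1-1)*49 + (c2-1)*7 + c3``; bijective over 1..343."""
    for c in (c1, c2, c3):
        if not 1 <= c <= 7:
            raise SequenceDomainError(f"class index {c} outside 1..7")
    return (c1 - 1) * 49 + (c2 - 1) * 7 + c3


def triad_label(index: int, alphabet: AlphabetMap = CTF_ALPHABET) -> str:
    """Class-label string of a 1-based triad index, e.g. 35 -> ``'C-RK-AGV'``."""
    if not 1 <= index <= 343:
        raise SequenceDomainError(f"triad index {index} outside 1..343")
    z = index - 1
    c1, c2, c3 = z // 49 + 1, (z // 7) % 7 + 1, z % 7 + 1
    return "-".join(alphabet.group_label(c) for c in (c1, c2, c3))


def compute_ctf(record, alphabet: AlphabetMap = CTF_ALPHABET) -> FeatureVector:
    """Conjoint triad feature: ``f_i = n_i / (L - 2)`` over the 343 ordered
    triad types of the reduced sequence.  Requires L >= 3."""
    residues = _residues_of(record)
    L = len(residues)
    if L < 3:
        raise SequenceDomainError(
            f"CTF requires sequence length >= 3, got {L} (f_i = n_i/(L-2))"
        )
    reduced = alphabet.reduce(residues)
    counts = np.zeros(343)
    for j in range(L - 2):
        counts[triad_index(reduced[j], reduced[j + 1], reduced[j + 2]) - 1] += 1
    return FeatureVector("ctf", counts / (L - 2))


def cgr_trajectory(record, config: CGRPolygonConfig = DEFAULT_CGR_CONFIG) -> np.ndarray:
    """Chaos-game trajectory: point i is the midpoint of point i-1 (point 0
    is the centre) and the vertex of residue i's group.  Returns an (L, 2)
    array; every point has norm strictly below 1."""
    residues = _residues_of(record)
    if not residues:
        raise SequenceDomainError("CGR undefined for an empty sequence")
    classes = config.vertex_groups.reduce(residues)
    points = np.empty((len(residues), 2))
    x = y = 0.0
    for i, k in enumerate(classes):
        vx, vy = config.vertices[k - 1]
        x = 0.5 * (x + vx)
        y = 0.5 * (y + vy)
        points[i, 0] = x
        points[i, 1] = y
    return points


def assign_segments(
    points: np.ndarray, config: CGRPolygonConfig = DEFAULT_CGR_CONFIG
) -> np.ndarray:
    """1-based sector index per trajectory point.

    Sector k spans polar angles [(k-1)pi/12, k*pi/12) counter-clockwise
    from the positive x-axis; a point exactly on a boundary ray goes to the
    lower-index adjacent sector, except that angle 0 belongs to sector 1.
    """
    pts = np.asarray(points, dtype=float)
    theta = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
    ratio = theta / (np.pi / 12)
    # boundary detection must tolerate rounding: an on-axis point can land
    # an ulp on either side of an integer multiple of pi/12
    nearest = np.rint(ratio)
    on_boundary = np.abs(ratio - nearest) < 1e-9
    seg = np.floor(ratio).astype(int) + 1
    k = nearest.astype(int)
    boundary_seg = np.where((k == 0) | (k >= config.n_segments), 1, k)
    seg = np.where(on_boundary, boundary_seg, seg)
    return seg


def cgr_features(
    points: np.ndarray, config: CGRPolygonConfig = DEFAULT_CGR_CONFIG
) -> FeatureVector:
    """Sector frequencies ``D_k = L_k / N`` of a trajectory (24-d)."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise SequenceDomainError("CGR features undefined for an empty trajectory")
    seg = assign_segments(pts, config)
    counts = np.bincount(seg - 1, minlength=config.n_segments).astype(float)
    return FeatureVector("cgr", counts / len(pts))


def compute_cgr(record, config: CGRPolygonConfig = DEFAULT_CGR_CONFIG) -> FeatureVector:
    """Trajectory plus sector counting in one call."""
    return cgr_features(cgr_trajectory(record, config), config)


def combine_features(blocks: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate single-block vectors of one record in canonical order
    (AAC, then CGR, then CTF).  A single block is returned unchanged."""
    if not blocks:
        raise ConfigurationError("no feature blocks given")
    block_names = tuple(b.feature_set for b in blocks)
    for name in block_names:
        if name not in _BLOCK_DIMS:
            raise ConfigurationError(
                f"combine_features takes single blocks, got {name!r}"
            )
    key = frozenset(block_names)
    if len(key) != len(block_names):
        raise ConfigurationError(f"repeated block in {block_names}")
    name = _CANONICAL_BY_BLOCKSET[key]
    expected_order = FEATURE_SETS[name]
    if block_names != expected_order:
        order = {b: i for i, b in enumerate(expected_order)}
        blocks = sorted(blocks, key=lambda b: order[b.feature_set])
    if len(blocks) == 1:
        return blocks[0]
    return FeatureVector(name, np.concatenate([b.values for b in blocks]))


def encode_record(
    record,
    feature_set: str = "aac+ctf",
    cgr_config: CGRPolygonConfig = DEFAULT_CGR_CONFIG,
    ctf_alphabet: AlphabetMap = CTF_ALPHABET,
) -> FeatureVector:
    """Encode one sequence under any of the seven feature sets."""
    name = canonical_feature_set(feature_set)
    parts = []
    for block in FEATURE_SETS[name]:
        if block == "aac":
            parts.append(compute_aac(record))
        elif block == "cgr":
            parts.append(compute_cgr(record, cgr_config))
        else:
            parts.append(compute_ctf(record, ctf_alphabet))
    return combine_features(parts)


def feature_names(feature_set: str) -> list[str]:
    """Stable per-column names: residue letters for AAC, ``S1..S24`` for
    CGR sectors, triad class-label strings (``C-RK-AGV``) for CTF."""
    name = canonical_feature_set(feature_set)
    out: list[str] = []
    for block in FEATURE_SETS[name]:
        if block == "aac":
            out.extend(STANDARD_AA)
        elif block == "cgr":
            out.extend(f"S{k}" for k in range(1, 25))
        else:
            out.extend(triad_label(i) for i in range(1, 344))
    return out


class _SequenceTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer base: fit is a no-op, transform encodes."""

    def fit(self, X, y=None):
        self._validate(X)
        self.n_features_in_ = 1  # one "column": the sequence itself
        return self

    @staticmethod
    def _validate(X) -> list[str]:
        if isinstance(X, (str, ProteinRecord)):
            raise TypeError("expected an iterable of sequences, got a single one")
        seqs = [_residues_of(x) for x in X]
        if not seqs:
            raise ValueError("empty sequence collection")
        return seqs

    def transform(self, X) -> np.ndarray:
        seqs = self._validate(X)
        return np.vstack([self._encode_one(s) for s in seqs])

    def _encode_one(self, seq: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


class AACEncoder(_SequenceTransformer):
    """Amino-acid composition transformer (n_sequences, 20)."""

    feature_names_ = list(STANDARD_AA)

    def _encode_one(self, seq: str) -> np.ndarray:
        return compute_aac(seq).values


class CTFEncoder(_SequenceTransformer):
    """Conjoint-triad transformer (n_sequences, 343)."""

    def __init__(self, alphabet: AlphabetMap = CTF_ALPHABET):
        self.alphabet = alphabet

    @property
    def feature_names_(self):
        return [triad_label(i, self.alphabet) for i in range(1, 344)]

    def _encode_one(self, seq: str) -> np.ndarray:
        return compute_ctf(seq, self.alphabet).values


class CGREncoder(_SequenceTransformer):
    """Chaos-game sector-frequency transformer (n_sequences, 24)."""

    feature_names_ = [f"S{k}" for k in range(1, 25)]

    def __init__(self, config: CGRPolygonConfig = DEFAULT_CGR_CONFIG):
        self.config = config

    def _encode_one(self, seq: str) -> np.ndarray:
        return compute_cgr(seq, self.config).values


class SequenceEncoder(_SequenceTransformer):
    """Encoder for any of the seven feature sets.

    Parameters
    ----------
    feature_set:
        ``aac``, ``cgr``, ``ctf`` or a ``+``-combination; block order is
        canonicalized to AAC, CGR, CTF.
    """

    def __init__(
        self,
        feature_set: str = "aac+ctf",
        cgr_config: CGRPolygonConfig = DEFAULT_CGR_CONFIG,
        ctf_alphabet: AlphabetMap = CTF_ALPHABET,
    ):
        self.feature_set = feature_set
        self.cgr_config = cgr_config
        self.ctf_alphabet = ctf_alphabet

    @property
    def canonical_name_(self) -> str:
        return canonical_feature_set(self.feature_set)

    @property
    def feature_names_(self):
        return feature_names(self.feature_set)

    def _encode_one(self, seq: str) -> np.ndarray:
        return encode_record(
            seq, self.feature_set, self.cgr_config, self.ctf_alphabet
        ).values


def plot_cgr(record, config: CGRPolygonConfig = DEFAULT_CGR_CONFIG, ax=None):
    """Render a trajectory with the 12-gon, vertex labels and the 24 sector
    boundaries overlaid.  Visual aid only; requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    verts = config.vertices
    ring = np.vstack([verts, verts[:1]])
    ax.plot(ring[:, 0], ring[:, 1], color="0.4", lw=1)
    for k in range(24):
        a = k * math.pi / 12
        ax.plot([0, math.cos(a)], [0, math.sin(a)], color="0.85", lw=0.6, zorder=0)
    for k, (x, y) in enumerate(verts, start=1):
        ax.annotate(
            f"V{k}:{config.vertex_groups.group_label(k)}",
            (x, y),
            xytext=(1.12 * x, 1.12 * y),
            ha="center",
            va="center",
            fontsize=7,
        )
    pts = cgr_trajectory(record, config)
    ax.scatter(pts[:, 0], pts[:, 1], s=4, color="tab:blue")
    ax.set_aspect("equal")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.axis("off")
    return ax
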