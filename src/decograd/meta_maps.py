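"""Meta-analytic maps from a coordinate-based study database.

Term-based route: studies whose TFIDF feature weight for a term exceeds a
threshold (default 0.001) form the selected sample; each study's peak
coordinates are convolved with a binary 10-mm sphere (max-combined) into a
modeled-activation map, and a per-cell 2x2 chi-square test of selected vs
unselected against active vs inactive yields a signed association map
(MKDA chi-square style).

Topic-based route: a latent Dirichlet allocation of the document corpus
provides p(word|topic) and p(topic|article); studies with
p(topic|article) above a threshold (default 0.05) are selected per topic
and fed through the same chi-square meta-analysis, labelled with the
topic's top words.

Modeled-activation maps can be rasterised on a volumetric grid
(``ma_map``) or evaluated directly at surface-vertex coordinates
(``ma_map_vertices``) — the chi-square step is agnostic to the cell space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation

__all__ = [
    "Study",
    "StudyDatabase",
    "Corpus",
    "TopicModel",
    "MetaAnalyticMap",
    "VolumeGrid",
    "select_by_term",
    "select_by_topic",
    "ma_map",
    "ma_map_vertices",
    "chi2_meta",
    "fit_topics",
    "topic_label",
    "build_term_maps",
    "build_topic_maps",
]


@dataclass
class Study:
    study_id: str
    coordinates: np.ndarray          # (m, 3) mm in the database's reference space
    features: dict[str, float]       # term -> TFIDF weight >= 0


@dataclass
class StudyDatabase:
    studies: list[Study]
    space: str = "synthetic"

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError("study_ids must be unique")
        for s in self.studies:
            s.coordinates = np.asarray(s.coordinates, dtype=float).reshape(-1, 3)
            if not np.all(np.isfinite(s.coordinates)):
                raise ValueError(f"study {s.study_id} has non-finite coordinates")

    @property
    def vocabulary(self) -> list[str]:
        vocab: set[str] = set()
        for s in self.studies:
            vocab.update(s.features)
        return sorted(vocab)

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]


@dataclass
class Corpus:
    """Token counts per document: ``counts[i, j]`` = occurrences of
    ``vocabulary[j]`` in ``doc_ids[i]``."""

    doc_ids: list[str]
    vocabulary: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise ValueError("counts shape must be (n_docs, n_vocab)")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        self._word_index = {w: j for j, w in enumerate(self.vocabulary)}
        self._doc_index = {d: i for i, d in enumerate(self.doc_ids)}

    def word_column(self, word: str) -> int:
        return self._word_index[word]

    def doc_row(self, doc_id: str) -> int:
        return self._doc_index[doc_id]


@dataclass
class TopicModel:
    word_topic: np.ndarray   # (n_topics, n_vocab), rows sum to 1: p(word|topic)
    doc_topic: np.ndarray    # (n_docs, n_topics), rows sum to 1: p(topic|article)
    vocabulary: list[str]
    doc_ids: list[str]

    @property
    def n_topics(self) -> int:
        return self.word_topic.shape[0]


@dataclass
class MetaAnalyticMap:
    labels: list[str]        # one term, or a topic's top words
    values: np.ndarray       # signed z-like association statistic per cell
    chi2: np.ndarray = field(repr=False, default=None)
    n_selected: int = 0
    n_unselected: int = 0
    selected_ids: list[str] | None = field(repr=False, default=None)
    word_probs: dict[str, float] | None = field(repr=False, default=None)  # p(word|topic) of the labels

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("map labels must be nonempty")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")

    @property
    def name(self) -> str:
        return "__".join(self.labels)


@dataclass
class VolumeGrid:
    """Isotropic rectangular grid: cell centres at
    ``origin + spacing * index`` along each axis."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]

    @classmethod
    def from_extent(cls, lo: float = -80.0, hi: float = 80.0, spacing: float = 4.0) -> "VolumeGrid":
        n = int(np.floor((hi - lo) / spacing)) + 1
        return cls(origin=np.array([lo, lo, lo], float), spacing=spacing, shape=(n, n, n))

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def cell_centers(self) -> np.ndarray:
        axes = [self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def select_by_term(db: StudyDatabase, term: str, threshold: float = 0.001) -> list[str]:
    """Study ids whose TFIDF feature weight for ``term`` exceeds ``threshold``."""
    if term not in db.vocabulary:
        raise KeyError(f"term {term!r} not in database vocabulary")
    selected = [s.study_id for s in db.studies if s.features.get(term, 0.0) > threshold]
    if not selected:
        raise ValueError(f"empty meta-analytic sample for term {term!r} at threshold {threshold}")
    return selected


def select_by_topic(doc_topic: np.ndarray, doc_ids: list[str], topic: int, threshold: float = 0.05) -> list[str]:
    """Document ids with p(topic|article) above ``threshold``."""
    doc_topic = np.asarray(doc_topic, dtype=float)
    if not 0 <= topic < doc_topic.shape[1]:
        raise IndexError(f"topic {topic} out of range")
    selected = [doc_ids[i] for i in np.flatnonzero(doc_topic[:, topic] > threshold)]
    if not selected:
        raise ValueError(f"empty meta-analytic sample for topic {topic} at threshold {threshold}")
    return selected


def _clip_coordinates(coords: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    outside = np.any((coords < lo) | (coords > hi), axis=1)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} coordinate(s) outside the grid; clipped to the boundary",
            RuntimeWarning,
            stacklevel=3,
        )
        coords = np.clip(coords, lo, hi)
    return coords


def ma_map(coordinates: np.ndarray, grid: VolumeGrid, radius_mm: float = 10.0) -> np.ndarray:
    """Modeled-activation map: binary sphere kernel, max-combined.

    A grid cell is 1 iff its centre lies within ``radius_mm`` of at least
    one peak coordinate (so duplicate coordinates are idempotent).
    Returns a flat array of length ``grid.n_cells``.
    """
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    out = np.zeros(grid.shape, dtype=np.uint8)
    if coords.shape[0] == 0:
        return out.ravel()
    lo = grid.origin
    hi = grid.origin + grid.spacing * (np.array(grid.shape) - 1)
    coords = _clip_coordinates(coords, lo, hi)
    r_cells = int(np.ceil(radius_mm / grid.spacing))
    for c in coords:
        idx = np.round((c - grid.origin) / grid.spacing).astype(int)
        sl = []
        ranges = []
        for d in range(3):
            a = max(idx[d] - r_cells, 0)
            b = min(idx[d] + r_cells + 1, grid.shape[d])
            sl.append(slice(a, b))
            ranges.append(grid.origin[d] + grid.spacing * np.arange(a, b))
        dx, dy, dz = np.meshgrid(*[rg - c[d] for d, rg in enumerate(ranges)], indexing="ij")
        ball = dx**2 + dy**2 + dz**2 <= radius_mm**2
        out[tuple(sl)] |= ball.astype(np.uint8)
    return out.ravel()


def ma_map_vertices(coordinates: np.ndarray, vertex_xyz: np.ndarray, radius_mm: float = 10.0) -> np.ndarray:
    """Vertex-space analogue of :func:`ma_map`: vertex active iff within
    ``radius_mm`` of any peak coordinate."""
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    vertex_xyz = np.asarray(vertex_xyz, dtype=float)
    if coords.shape[0] == 0:
        return np.zeros(vertex_xyz.shape[0], dtype=np.uint8)
    d2 = ((vertex_xyz[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return (d2.min(axis=1) <= radius_mm**2).astype(np.uint8)


def chi2_meta(selected_maps: np.ndarray, unselected_maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell 2x2 Pearson chi-square of group membership vs activation.

    Parameters
    ----------
    selected_maps, unselected_maps : (n_studies, n_cells) binary arrays

    Returns
    -------
    z : signed z-like statistic, ``sign(P(act|sel) - P(act|unsel)) * sqrt(chi2)``
    chi2 : the raw chi-square values

    Cells with a zero margin (all active or all inactive, or an empty
    group) are set to 0.
    """
    sel = np.atleast_2d(np.asarray(selected_maps))
    uns = np.atleast_2d(np.asarray(unselected_maps))
    if sel.shape[0] == 0 or uns.shape[0] == 0:
        raise ValueError("both study groups must be nonempty")
    if sel.shape[1] != uns.shape[1]:
        raise ValueError(f"grid mismatch: {sel.shape[1]} vs {uns.shape[1]} cells")
    n1, n2 = sel.shape[0], uns.shape[0]
    n = n1 + n2
    a = sel.sum(axis=0).astype(float)      # selected, active
    c = uns.sum(axis=0).astype(float)      # unselected, active
    b = n1 - a
    d = n2 - c
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
        sign = np.sign(a / n1 - c / n2)
    z = sign * np.sqrt(chi2)
    return z, chi2


def fit_topics(corpus: Corpus, n_topics: int = 200, seed: int | None = None, max_iter: int = 30) -> TopicModel:
    """Latent Dirichlet allocation of the corpus (batch variational fit).

    Returns row-normalised p(word|topic) and p(topic|article) matrices;
    the fit is fully determined by ``seed``.
    """
    if len(corpus.doc_ids) == 0:
        raise ValueError("corpus is empty")
    if len(corpus.vocabulary) < n_topics:
        raise ValueError(
            f"vocabulary ({len(corpus.vocabulary)}) smaller than n_topics ({n_topics})"
        )
    lda = LatentDirichletAllocation(
        n_components=n_topics, random_state=seed, learning_method="batch", max_iter=max_iter
    )
    doc_topic = lda.fit_transform(corpus.counts)
    word_topic = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    doc_topic = doc_topic / doc_topic.sum(axis=1, keepdims=True)
    return TopicModel(
        word_topic=word_topic,
        doc_topic=doc_topic,
        vocabulary=list(corpus.vocabulary),
        doc_ids=list(corpus.doc_ids),
    )


def topic_label(model: TopicModel, topic: int, n_words: int = 3) -> list[str]:
    """Top-probability words of a topic; ties broken lexicographically."""
    if not 1 <= n_words <= len(model.vocabulary):
        raise ValueError("n_words out of range")
    p = model.word_topic[topic]
    order = sorted(range(len(p)), key=lambda j: (-p[j], model.vocabulary[j]))
    return [model.vocabulary[j] for j in order[:n_words]]


def _meta_from_selection(
    selected_ids: list[str],
    study_maps: dict[str, np.ndarray],
    labels: list[str],
    word_probs: dict[str, float] | None = None,
) -> MetaAnalyticMap:
    sel_set = set(selected_ids)
    sel = np.array([study_maps[i] for i in study_maps if i in sel_set])
    uns = np.array([study_maps[i] for i in study_maps if i not in sel_set])
    z, chi2 = chi2_meta(sel, uns)
    return MetaAnalyticMap(labels=labels, values=z, chi2=chi2,
                           n_selected=sel.shape[0], n_unselected=uns.shape[0],
                           selected_ids=list(selected_ids), word_probs=word_probs)


def build_term_maps(
    db: StudyDatabase,
    study_maps: dict[str, np.ndarray],
    threshold: float = 0.001,
    terms: list[str] | None = None,
) -> tuple[list[MetaAnalyticMap], list[str]]:
    """One chi-square meta-analytic map per usable vocabulary term.

    ``study_maps`` maps study_id to its modeled-activation map (from
    :func:`ma_map` or :func:`ma_map_vertices`). Terms whose selection is
    empty or exhaustive (no unselected studies) are skipped and reported.
    """
    maps: list[MetaAnalyticMap] = []
    skipped: list[str] = []
    for term in terms if terms is not None else db.vocabulary:
        try:
            selected = select_by_term(db, term, threshold)
        except (ValueError, KeyError):
            skipped.append(term)
            continue
        if len(selected) == len(study_maps):
            skipped.append(term)
            continue
        maps.append(_meta_from_selection(selected, study_maps, [term]))
    return maps, skipped


def build_topic_maps(
    model: TopicModel,
    study_maps: dict[str, np.ndarray],
    threshold: float = 0.05,
    n_words: int = 3,
) -> tuple[list[MetaAnalyticMap], list[int]]:
    """One chi-square meta-analytic map per usable topic, labelled with the
    topic's top words."""
    maps: list[MetaAnalyticMap] = []
    skipped: list[int] = []
    for t in range(model.n_topics):
        try:
            selected = select_by_topic(model.doc_topic, model.doc_ids, t, threshold)
        except ValueError:
            skipped.append(t)
            continue
        if len(selected) == len(study_maps):
            skipped.append(t)
            continue
        labels = topic_label(model, t, n_words)
        word_probs = {
            w: float(model.word_topic[t, model.vocabulary.index(w)]) for w in labels
        }
        maps.append(_meta_from_selection(selected, study_maps, labels, word_probs))
    return maps, skipped
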