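"""Synthetic inputs with planted ground truth.

Every stage of the framework can be exercised without external downloads:

* ``synth_sphere`` — quasi-uniform spherical mesh with a medial-wall cap,
* ``synth_connectome`` — connectivity from a planted 1-D latent axis, so
  the principal gradient has a known target,
* ``synth_database`` — a coordinate-based study database with planted
  topics: disjoint-leaning word distributions and spatial focus centres,
  study-level topic mixtures, word counts, peak coordinates, and TFIDF
  features,
* ``synth_annotations`` — crowd-style category votes with a known true
  category per word,
* ``synth_world`` — the coupled scenario: the latent connectome axis runs
  pole to pole on the sphere and two "end" topics are planted at the
  poles, so the terminal segments of the principal gradient have known
  generating topics.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction.text import TfidfTransformer

from .connectome import DenseConnectome
from .decoder import SphereMesh
from .meta_maps import Corpus, Study, StudyDatabase, ma_map_vertices
from .semantics import CATEGORIES, AnnotationSet

__all__ = [
    "SyntheticTruth",
    "SyntheticWorld",
    "synth_sphere",
    "synth_connectome",
    "synth_database",
    "synth_annotations",
    "synth_world",
]


@dataclass
class SyntheticTruth:
    latent_axis: np.ndarray | None = None          # per-cortex-vertex t in [0, 1]
    topic_centers: np.ndarray | None = None        # (n_topics, 3) unit vectors
    topic_word: np.ndarray | None = None           # (n_topics, n_vocab)
    doc_topic: np.ndarray | None = None            # (n_docs, n_topics) mixtures
    dominant_topic: np.ndarray | None = None       # per-study planted dominant topic
    signature_words: dict[int, list[str]] = field(default_factory=dict)
    word_categories: dict[str, str] = field(default_factory=dict)
    end_topics: tuple[int, int] | None = None      # topics planted at (low-t, high-t) poles


@dataclass
class SyntheticWorld:
    """Coupled synthetic inputs for an end-to-end run."""

    mesh: SphereMesh
    connectome: DenseConnectome
    database: StudyDatabase
    corpus: Corpus
    annotations: AnnotationSet
    truth: SyntheticTruth
    brain_radius: float
    study_maps: dict[str, np.ndarray]   # study_id -> full-mesh binary activation map


def synth_sphere(n_vertices: int, medial_fraction: float = 0.1, seed: int | None = None) -> SphereMesh:
    """Fibonacci-lattice unit sphere with a contiguous medial-wall cap.

    The cap is centred on the +x axis (perpendicular to the z axis used as
    the latent direction elsewhere) and covers ``medial_fraction`` of the
    sphere area.
    """
    if not 0 <= medial_fraction < 1:
        raise ValueError("medial_fraction must lie in [0, 1)")
    i = np.arange(n_vertices)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n_vertices
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    coords = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    # spherical cap of area fraction f has cos(angle) = 1 - 2f
    cortex = coords[:, 0] < (1 - 2 * medial_fraction) if medial_fraction > 0 else np.ones(n_vertices, bool)
    return SphereMesh(coordinates=coords, cortex_mask=cortex)


def synth_connectome(
    n_vertices: int = 2000,
    lengthscale: float = 0.2,
    noise_sd: float = 0.05,
    seed: int | None = None,
    latent: np.ndarray | None = None,
) -> tuple[DenseConnectome, SyntheticTruth]:
    """Connectome with a planted 1-D latent axis.

    Connectivity decays exponentially with latent distance,
    ``r_ij = exp(-|t_i - t_j| / lengthscale)``, plus symmetric Gaussian
    noise; the diagonal is 1 and values are clipped to [-1, 1]. The
    principal gradient of this matrix recovers t by construction.
    """
    if n_vertices < 50 and latent is None:
        raise ValueError("n_vertices must be >= 50")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_vertices) if latent is None else np.asarray(latent, float)
    n = t.size
    r = np.exp(-np.abs(t[:, None] - t[None, :]) / lengthscale)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        r = r + (noise + noise.T) / np.sqrt(2)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return DenseConnectome(values=r, value_kind="r"), SyntheticTruth(latent_axis=t)


def _topic_word_distributions(
    rng: np.random.Generator, n_topics: int, vocabulary: list[str], signature_mass: float = 20.0
) -> tuple[np.ndarray, dict[int, list[str]]]:
    """Dirichlet word distributions concentrated on disjoint signature blocks."""
    v = len(vocabulary)
    block = v // n_topics
    word_topic = np.empty((n_topics, v))
    signatures: dict[int, list[str]] = {}
    for t in range(n_topics):
        alpha = np.full(v, 0.01)
        sig = slice(t * block, (t + 1) * block)
        alpha[sig] = signature_mass / block
        word_topic[t] = rng.dirichlet(alpha)
        signatures[t] = vocabulary[sig]
    return word_topic, signatures


def synth_database(
    n_studies: int = 500,
    n_topics: int = 20,
    vocab_size: int = 400,
    coords_per_study: int = 8,
    seed: int | None = None,
    topic_centers: np.ndarray | None = None,
    brain_radius: float = 70.0,
    doc_length: int = 150,
    coord_jitter: float = 6.0,
    on_sphere: bool = True,
    dominant_weight: tuple[float, float] = (0.7, 0.9),
    coord_sampler=None,
) -> tuple[StudyDatabase, Corpus, SyntheticTruth]:
    """Coordinate-based study database with planted topics.

    Each topic owns a spatial focus centre (unit vector, scaled by
    ``brain_radius`` mm) and a word distribution concentrated on a
    disjoint signature block of the vocabulary. Each study draws a topic
    mixture dominated by one topic (dominant mass uniform in
    ``dominant_weight``), multinomial word counts from the mixed word
    distribution, and peak coordinates around the centres of
    mixture-sampled topics. Features are l2-normalised TFIDF weights of
    the word counts (zero count -> zero feature).

    ``coord_sampler(topic, rng) -> (3,) mm coordinate`` overrides the
    default centre-plus-jitter spatial model; :func:`synth_world` uses it
    to couple coordinates to the latent connectome axis.
    """
    if vocab_size < 5 * n_topics:
        raise ValueError("vocab_size must be at least 5 * n_topics")
    rng = np.random.default_rng(seed)
    vocabulary = [f"w{j:04d}" for j in range(vocab_size)]
    word_topic, signatures = _topic_word_distributions(rng, n_topics, vocabulary)

    if topic_centers is None:
        raw = rng.standard_normal((n_topics, 3))
        topic_centers = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    topic_centers = np.asarray(topic_centers, float)

    doc_topic = np.empty((n_studies, n_topics))
    dominant = np.empty(n_studies, dtype=int)
    counts = np.empty((n_studies, vocab_size), dtype=np.int64)
    all_coords: list[np.ndarray] = []
    for s in range(n_studies):
        dom = s % n_topics                      # balanced planting
        w_dom = rng.uniform(*dominant_weight)
        rest = rng.dirichlet(np.full(n_topics - 1, 0.3)) * (1 - w_dom)
        mix = np.insert(rest, dom, w_dom)
        doc_topic[s] = mix
        dominant[s] = dom
        counts[s] = rng.multinomial(doc_length, mix @ word_topic)
        pts = np.empty((coords_per_study, 3))
        for c in range(coords_per_study):
            topic = dom if rng.uniform() < 0.8 else rng.choice(n_topics, p=mix)
            if coord_sampler is not None:
                p = coord_sampler(int(topic), rng)
            else:
                p = topic_centers[topic] * brain_radius + rng.normal(0, coord_jitter, 3)
            if on_sphere:
                p = p / np.linalg.norm(p) * brain_radius
            pts[c] = p
        all_coords.append(pts)

    tfidf = TfidfTransformer(norm="l2", smooth_idf=True).fit_transform(counts).toarray()
    studies = []
    for s in range(n_studies):
        nz = np.flatnonzero(tfidf[s])
        features = {vocabulary[j]: float(tfidf[s, j]) for j in nz}
        studies.append(Study(study_id=f"s{s:05d}", coordinates=all_coords[s], features=features))
    db = StudyDatabase(studies=studies)
    corpus = Corpus(doc_ids=db.study_ids, vocabulary=vocabulary, counts=counts)
    truth = SyntheticTruth(
        topic_centers=topic_centers,
        topic_word=word_topic,
        doc_topic=doc_topic,
        dominant_topic=dominant,
        signature_words=signatures,
    )
    return db, corpus, truth


def synth_annotations(
    vocabulary: list[str],
    functional_fraction: float = 0.5,
    n_raters: int = 10,
    agreement: float = 0.9,
    seed: int | None = None,
) -> tuple[AnnotationSet, dict[str, str]]:
    """Crowd-style category votes with planted true categories.

    Each word's true category is Functional with probability
    ``functional_fraction`` (the rest split evenly over the other three);
    each rater votes the true category with probability ``agreement`` and
    a uniformly random other category otherwise.
    """
    if not 0 <= functional_fraction <= 1:
        raise ValueError("functional_fraction must lie in [0, 1]")
    if not 0.25 <= agreement <= 1:
        raise ValueError("agreement must lie in [0.25, 1]")
    rng = np.random.default_rng(seed)
    others = [c for c in CATEGORIES if c != "Functional"]
    votes: dict[str, dict[str, int]] = {}
    true_cats: dict[str, str] = {}
    for word in vocabulary:
        true = "Functional" if rng.uniform() < functional_fraction else others[rng.integers(3)]
        true_cats[word] = true
        counts = dict.fromkeys(CATEGORIES, 0)
        wrong = [c for c in CATEGORIES if c != true]
        for _ in range(n_raters):
            if rng.uniform() < agreement:
                counts[true] += 1
            else:
                counts[wrong[rng.integers(3)]] += 1
        votes[word] = {c: v for c, v in counts.items() if v > 0}
    return AnnotationSet(votes=votes), true_cats


def synth_world(
    n_vertices: int = 2000,
    n_studies: int = 500,
    n_topics: int = 20,
    vocab_size: int = 400,
    medial_fraction: float = 0.1,
    lengthscale: float = 0.2,
    noise_sd: float = 0.05,
    coords_per_study: int = 8,
    brain_radius: float = 70.0,
    ma_radius: float = 10.0,
    t_noise: float = 0.15,
    spatial_scale: float = 0.7,
    t_scale: float = 0.12,
    coord_jitter: float = 4.0,
    functional_fraction: float = 0.5,
    agreement: float = 0.9,
    seed: int | None = None,
) -> SyntheticWorld:
    """The coupled scenario tying connectome, sphere and database together.

    The latent connectome axis t blends the normalised z coordinate of
    the cortex vertices with a per-vertex random component (fraction
    ``t_noise``), rank-normalised to [0, 1] — like a real gradient it
    follows the cortical geometry only approximately, carrying fine
    topography of its own. Topic 0 is planted at the south pole (t = 0
    end) and topic 1 at the north pole (t = 1 end); the remaining topic
    centres are drawn away from the poles (|z| < 0.5).

    Study peak coordinates are sampled at cortex vertices with weight
    proportional to a spatial kernel around the topic centre (chord-scale
    ``spatial_scale``) times a latent-axis kernel around the topic's
    nominal t (width ``t_scale``), plus ``coord_jitter`` mm of scatter.
    The latent-axis factor couples activation topography to the gradient
    the way task activations follow function rather than pure geometry,
    so a correctly aligned meta-analytic map beats every rotated null.
    Modeled-activation maps use a binary kernel of ``ma_radius`` mm on
    the mesh vertices scaled to ``brain_radius`` mm.
    """
    rng = np.random.default_rng(seed)
    s_mesh, s_conn, s_db, s_ann = rng.integers(0, 2**31 - 1, size=4)

    mesh = synth_sphere(n_vertices, medial_fraction, seed=int(s_mesh))
    cortex = mesh.cortex_mask
    t_geom = (mesh.coordinates[cortex, 2] + 1.0) / 2.0
    blend = (1 - t_noise) * t_geom + t_noise * rng.uniform(size=t_geom.size)
    t = np.argsort(np.argsort(blend)) / (t_geom.size - 1)
    connectome, conn_truth = synth_connectome(
        lengthscale=lengthscale, noise_sd=noise_sd, seed=int(s_conn), latent=t
    )

    centers = np.empty((n_topics, 3))
    centers[0] = [0.0, 0.0, -1.0]
    centers[1] = [0.0, 0.0, 1.0]
    for j in range(2, n_topics):
        while True:
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            if abs(v[2]) < 0.5:   # keep the poles unambiguous for the end topics
                centers[j] = v
                break

    cortex_xyz = mesh.coordinates[cortex]
    t_nominal = (centers[:, 2] + 1.0) / 2.0
    weights = []
    for j in range(n_topics):
        chord2 = ((cortex_xyz - centers[j]) ** 2).sum(axis=1)
        w = np.exp(-chord2 / (2 * spatial_scale**2)) * np.exp(
            -((t - t_nominal[j]) ** 2) / (2 * t_scale**2)
        )
        weights.append(w / w.sum())

    def coord_sampler(topic: int, srng: np.random.Generator) -> np.ndarray:
        i = srng.choice(t.size, p=weights[topic])
        return cortex_xyz[i] * brain_radius + srng.normal(0, coord_jitter, 3)

    db, corpus, truth = synth_database(
        n_studies=n_studies,
        n_topics=n_topics,
        vocab_size=vocab_size,
        coords_per_study=coords_per_study,
        seed=int(s_db),
        topic_centers=centers,
        brain_radius=brain_radius,
        coord_sampler=coord_sampler,
    )
    annotations, word_cats = synth_annotations(
        corpus.vocabulary, functional_fraction, agreement=agreement, seed=int(s_ann)
    )
    truth.latent_axis = conn_truth.latent_axis
    truth.word_categories = word_cats
    truth.end_topics = (0, 1)

    vertex_xyz = mesh.coordinates * brain_radius
    study_maps = {
        s.study_id: ma_map_vertices(s.coordinates, vertex_xyz, radius_mm=ma_radius)
        for s in db.studies
    }
    return SyntheticWorld(
        mesh=mesh,
        connectome=connectome,
        database=db,
        corpus=corpus,
        annotations=annotations,
        truth=truth,
        brain_radius=brain_radius,
        study_maps=study_maps,
    )
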