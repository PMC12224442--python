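"""Format readers and writers: GIFTI surface data, TSV tables, JSON.

Dense matrices travel either as whitespace/comma-delimited text or as .npy
arrays; per-vertex maps (gradients, segment labels, pseudo-activation
maps) are written as GIFTI functional/label files; tables as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectome import DenseConnectome, GradientSet
from .decoder import SphereMesh
from .meta_maps import Corpus, Study, StudyDatabase
from .segmentation import Segmentation
from .semantics import AnnotationSet

__all__ = [
    "read_connectome",
    "write_gradients",
    "read_gradients_table",
    "write_func_gii",
    "read_func_gii",
    "write_label_gii",
    "write_surf_gii",
    "read_surf_gii",
    "write_mesh",
    "read_mesh",
    "write_segmentation",
    "write_database",
    "read_database",
    "write_corpus",
    "read_corpus",
    "write_annotations",
    "read_annotations",
]


def read_connectome(path: str | Path, value_kind: str = "z", vertex_table: str | Path | None = None) -> DenseConnectome:
    """Load a dense connectome from .npy or delimited text."""
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        values = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
    vertex_ids = None
    if vertex_table is not None:
        table = pd.read_csv(vertex_table, sep="\t")
        vertex_ids = table["vertex_id"].astype(str).tolist()
    return DenseConnectome(values=values, vertex_ids=vertex_ids, value_kind=value_kind)


def write_func_gii(path: str | Path, values: np.ndarray) -> None:
    arr = nib.gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[arr]), str(path))


def read_func_gii(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)


def write_label_gii(path: str | Path, labels: np.ndarray) -> None:
    arr = nib.gifti.GiftiDataArray(
        np.asarray(labels, dtype=np.int32), intent="NIFTI_INTENT_LABEL"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[arr]), str(path))


def write_surf_gii(path: str | Path, coordinates: np.ndarray, faces: np.ndarray | None = None) -> None:
    darrays = [
        nib.gifti.GiftiDataArray(
            np.asarray(coordinates, dtype=np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    ]
    if faces is None:
        faces = np.zeros((0, 3))
    darrays.append(
        nib.gifti.GiftiDataArray(np.asarray(faces, dtype=np.int32), intent="NIFTI_INTENT_TRIANGLE")
    )
    nib.save(nib.gifti.GiftiImage(darrays=darrays), str(path))


def read_surf_gii(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            return np.asarray(da.data, dtype=float)
    raise ValueError(f"no POINTSET array in {path}")


def write_mesh(directory: str | Path, mesh: SphereMesh, stem: str = "sphere") -> None:
    directory = Path(directory)
    write_surf_gii(directory / f"{stem}.surf.gii", mesh.coordinates)
    np.savetxt(directory / f"{stem}_cortex_mask.txt", mesh.cortex_mask.astype(int), fmt="%d")
    np.savetxt(directory / f"{stem}_hemisphere.txt", mesh.hemisphere, fmt="%d")


def read_mesh(directory: str | Path, stem: str = "sphere") -> SphereMesh:
    directory = Path(directory)
    coords = read_surf_gii(directory / f"{stem}.surf.gii")
    mask = np.loadtxt(directory / f"{stem}_cortex_mask.txt").astype(bool)
    hemi_path = directory / f"{stem}_hemisphere.txt"
    hemi = np.loadtxt(hemi_path).astype(int) if hemi_path.exists() else None
    return SphereMesh(coordinates=coords, cortex_mask=mask, hemisphere=hemi)


def write_gradients(directory: str | Path, gradients: GradientSet, stem: str = "gradient") -> None:
    """One GIFTI functional file per component plus an eigenvalue table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for j in range(gradients.n_components):
        write_func_gii(directory / f"{stem}_{j + 1:02d}.func.gii", gradients.components[:, j])
    pd.DataFrame(
        {
            "component": np.arange(1, gradients.n_components + 1),
            "eigenvalue": gradients.eigenvalues,
            "explained_variance": gradients.explained_variance,
        }
    ).to_csv(directory / f"{stem}_eigenvalues.tsv", sep="\t", index=False)


def read_gradients_table(directory: str | Path, stem: str = "gradient") -> GradientSet:
    directory = Path(directory)
    table = pd.read_csv(directory / f"{stem}_eigenvalues.tsv", sep="\t")
    comps = [
        read_func_gii(directory / f"{stem}_{int(c):02d}.func.gii") for c in table["component"]
    ]
    return GradientSet(
        components=np.column_stack(comps),
        eigenvalues=table["eigenvalue"].to_numpy(),
        explained_variance=table["explained_variance"].to_numpy(),
    )


def write_segmentation(directory: str | Path, seg: Segmentation, vertex_ids: list[str] | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{seg.method.lower()}_k{seg.k:02d}"
    write_label_gii(directory / f"{stem}.label.gii", seg.labels)
    n = seg.labels.size
    ids = vertex_ids if vertex_ids is not None else [f"v{i:05d}" for i in range(n)]
    pd.DataFrame(
        {"vertex_id": ids, "method": seg.method, "k": seg.k, "label": seg.labels}
    ).to_csv(directory / f"{stem}.tsv", sep="\t", index=False)


def write_database(path: str | Path, db: StudyDatabase) -> None:
    payload = {
        "space": db.space,
        "studies": [
            {
                "study_id": s.study_id,
                "coordinates": np.asarray(s.coordinates).tolist(),
                "features": s.features,
            }
            for s in db.studies
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_database(path: str | Path) -> StudyDatabase:
    payload = json.loads(Path(path).read_text())
    studies = [
        Study(
            study_id=s["study_id"],
            coordinates=np.asarray(s["coordinates"], dtype=float),
            features={k: float(v) for k, v in s["features"].items()},
        )
        for s in payload["studies"]
    ]
    return StudyDatabase(studies=studies, space=payload.get("space", "synthetic"))


def write_corpus(directory: str | Path, corpus: Corpus, stem: str = "corpus") -> None:
    directory = Path(directory)
    np.save(directory / f"{stem}_counts.npy", corpus.counts)
    (directory / f"{stem}_vocabulary.txt").write_text("\n".join(corpus.vocabulary) + "\n")
    (directory / f"{stem}_doc_ids.txt").write_text("\n".join(corpus.doc_ids) + "\n")


def read_corpus(directory: str | Path, stem: str = "corpus") -> Corpus:
    directory = Path(directory)
    counts = np.load(directory / f"{stem}_counts.npy")
    vocab = (directory / f"{stem}_vocabulary.txt").read_text().split()
    doc_ids = (directory / f"{stem}_doc_ids.txt").read_text().split()
    return Corpus(doc_ids=doc_ids, vocabulary=vocab, counts=counts)


def write_annotations(path: str | Path, annotations: AnnotationSet) -> None:
    rows = []
    for word, counts in annotations.votes.items():
        for category, n in counts.items():
            rows.append({"word": word, "category": category, "votes": n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> AnnotationSet:
    table = pd.read_csv(path, sep="\t")
    votes: dict[str, dict[str, int]] = {}
    for row in table.itertuples():
        votes.setdefault(row.word, {})[row.category] = int(row.votes)
    return AnnotationSet(votes=votes)
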