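"""PCA statistical shape model over vertex-corresponded meshes.

Training meshes must share vertex count and face topology (correspondence
is assumed given, e.g. from a deformed template); each shape is centred at
its own vertex centroid before fitting, so the model is position-free and
placement is a separate translation. Decoding is the pure linear map
``mean + weights @ components``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import TriangleMesh

__all__ = ["ShapeModel", "fit_shape_pca", "decode_shape", "encode_shape"]


@dataclass(frozen=True)
class ShapeModel:
    """Mean shape, orthonormal components and the shared face topology.

    ``components`` rows are unit-norm directions in flattened vertex space
    (3V); weights therefore carry units of mm along each component.
    """

    mean_shape: np.ndarray  # (3V,) mm
    components: np.ndarray  # (n_components, 3V), orthonormal rows
    explained_variance: np.ndarray  # (n_components,), mm^2, non-increasing
    face_topology: np.ndarray  # (F, 3)

    def __post_init__(self):
        object.__setattr__(self, "mean_shape",
                           np.asarray(self.mean_shape, dtype=np.float64))
        object.__setattr__(self, "components",
                           np.asarray(self.components, dtype=np.float64))
        object.__setattr__(self, "explained_variance",
                           np.asarray(self.explained_variance, dtype=np.float64))
        object.__setattr__(self, "face_topology",
                           np.asarray(self.face_topology, dtype=np.int64))

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.mean_shape.size // 3

    def save(self, path) -> None:
        """Serialise to a single ``.npz`` archive."""
        np.savez(
            Path(path),
            mean_shape=self.mean_shape,
            components=self.components,
            explained_variance=self.explained_variance,
            face_topology=self.face_topology,
        )

    @classmethod
    def load(cls, path) -> "ShapeModel":
        with np.load(Path(path)) as data:
            return cls(
                mean_shape=data["mean_shape"],
                components=data["components"],
                explained_variance=data["explained_variance"],
                face_topology=data["face_topology"],
            )


def _check_correspondence(meshes: list[TriangleMesh]) -> None:
    ref = meshes[0]
    for k, m in enumerate(meshes[1:], start=1):
        if m.n_vertices != ref.n_vertices or not np.array_equal(m.faces, ref.faces):
            raise ValueError(
                f"mesh {k} topology does not match mesh 0 "
                "(vertex correspondence is required)"
            )


def fit_shape_pca(
    training_meshes: list[TriangleMesh],
    n_components: int,
    center: bool = True,
) -> ShapeModel:
    """Fit the leading principal components of vertex-coordinate variation.

    ``center=True`` (default) translates each training shape to its own
    vertex centroid first, making the model position-free.
    """
    if len(training_meshes) < 2:
        raise ValueError("need at least 2 training meshes")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > len(training_meshes) - 1:
        raise ValueError(
            f"n_components={n_components} exceeds n_shapes-1="
            f"{len(training_meshes) - 1}"
        )
    _check_correspondence(training_meshes)
    rows = []
    for m in training_meshes:
        v = m.vertices
        if center:
            v = v - v.mean(axis=0)
        rows.append(v.ravel())
    data = np.stack(rows)  # (n, 3V)
    mean = data.mean(axis=0)
    centered = data - mean
    # SVD of the data matrix gives the covariance eigenvectors directly
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    variance = svals**2 / (len(data) - 1)
    return ShapeModel(
        mean_shape=mean,
        components=vt[:n_components],
        explained_variance=variance[:n_components],
        face_topology=training_meshes[0].faces,
    )


def decode_shape(model: ShapeModel, weights) -> TriangleMesh:
    """Weights -> mesh: vertices are ``mean + weights @ components``."""
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (model.n_components,):
        raise ValueError(
            f"expected {model.n_components} weights, got shape {w.shape}"
        )
    flat = model.mean_shape + w @ model.components
    return TriangleMesh(flat.reshape(-1, 3), model.face_topology)


def encode_shape(
    model: ShapeModel,
    mesh: TriangleMesh,
    return_residual: bool = False,
    center: bool = False,
):
    """Least-squares projection of ``vertices - mean`` onto the components.

    ``center=True`` removes the mesh's own vertex centroid first (useful
    when encoding a raw, uncentred training mesh against the position-free
    fit). With ``return_residual=True`` also returns the norm (mm) of the
    part of the shape not captured by the model span.
    """
    if mesh.n_vertices != model.n_vertices or not np.array_equal(
        mesh.faces, model.face_topology
    ):
        raise ValueError("mesh topology does not match the shape model")
    v = mesh.vertices
    if center:
        v = v - v.mean(axis=0)
    diff = v.ravel() - model.mean_shape
    w = model.components @ diff
    if return_residual:
        residual = diff - w @ model.components
        return w, float(np.linalg.norm(residual))
    return w
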