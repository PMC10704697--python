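"""Protein graphs from contact-probability maps.

A protein of length ``L`` becomes a graph with one node per residue and
weighted edges given by the predicted contact probabilities, so the adjacency
retains every possible residue pair rather than a hard-thresholded topology.
Before normalization the raw diagonal is discarded and unit self-loops are
added, which keeps isolated residues well-defined.  The default normalization
is the symmetric degree scaling

    A_hat = D^{-1/2} (A + I) D^{-1/2},

whose spectral radius is at most 1, keeping repeated graph-convolution
propagation well-scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, ShapeError
from .io import ContactMap, ProteinRecord

ADJACENCY_SCHEMES = ("sym_degree", "row_stochastic", "none")


@dataclass
class ProteinGraph:
    """Normalized adjacency plus node features for one protein."""

    node_features: np.ndarray  # L x C
    adjacency: np.ndarray      # L x L, normalized
    raw_contact: ContactMap


def normalize_adjacency(adjacency: np.ndarray, scheme: str = "sym_degree") -> np.ndarray:
    """Normalize a non-negative adjacency that already includes self-loops."""
    if scheme not in ADJACENCY_SCHEMES:
        raise ConfigError(
            f"unknown adjacency normalization {scheme!r}; known: {ADJACENCY_SCHEMES}"
        )
    A = np.asarray(adjacency, dtype=float)
    if scheme == "none":
        return A
    deg = A.sum(axis=1)
    if scheme == "row_stochastic":
        return A / deg[:, None]
    # self-loops guarantee deg > 0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def build_graph(
    record: ProteinRecord | ContactMap | np.ndarray,
    node_features: np.ndarray,
    threshold: float = 0.0,
    normalization: str = "sym_degree",
) -> ProteinGraph:
    """Build the residue graph for one protein.

    Parameters
    ----------
    record : a :class:`ProteinRecord` (its contact map is used), a
        :class:`ContactMap`, or a raw square array.
    node_features : ``L x C`` node-feature matrix, typically the hybrid
        feature after adaptive re-weighting.
    threshold : contact probabilities strictly below this are zeroed before
        self-loops are added.  Must lie in ``[0, 1)``; the default ``0.0``
        keeps the full probability-weighted adjacency.
    normalization : ``sym_degree`` (default), ``row_stochastic`` or ``none``.
    """
    if isinstance(record, ProteinRecord):
        if record.contact is None:
            raise ShapeError(f"protein {record.id}: no contact map")
        contact = record.contact
    elif isinstance(record, ContactMap):
        contact = record
    else:
        contact = ContactMap(matrix=np.asarray(record, dtype=float))

    if not (0.0 <= threshold < 1.0):
        raise ConfigError(
            f"contact threshold must lie in [0, 1), got {threshold} "
            "(1.0 would erase all contacts, including certain ones)"
        )
    node_features = np.asarray(node_features, dtype=float)
    L = contact.L
    if node_features.shape[0] != L:
        raise ShapeError(
            f"node features have {node_features.shape[0]} rows but the contact "
            f"map is {L}x{L}"
        )

    A = contact.matrix.copy()
    A[A < threshold] = 0.0
    np.fill_diagonal(A, 0.0)  # raw diagonal is replaced by unit self-loops
    if L > 0 and not A.any():
        warnings.warn(
            "adjacency is all-zero after thresholding; proceeding with "
            "self-loops only (disconnected-residue graph)",
            stacklevel=2,
        )
    A = A + np.eye(L)
    A_hat = normalize_adjacency(A, normalization)
    if not np.all(np.isfinite(A_hat)):
        raise ShapeError("normalized adjacency contains non-finite entries")
    return ProteinGraph(node_features=node_features, adjacency=A_hat, raw_contact=contact)
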