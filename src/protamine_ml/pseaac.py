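"""Pseudo amino acid composition (type-I PseAAC) featurization.

A protein of length :math:`L` is mapped to a :math:`20 + \\lambda` vector:
the first 20 components are the residue frequencies :math:`f_u = n_u / L`
(alphabetical one-letter order) and the remaining :math:`\\lambda`
components are sequence-order correlation factors

.. math::

    \\theta_k = \\frac{1}{L-k} \\sum_{i=1}^{L-k} \\Theta(R_i, R_{i+k}),
    \\qquad
    \\Theta(a, b) = \\frac{1}{3}\\left[(h_1(a)-h_1(b))^2
        + (h_2(a)-h_2(b))^2 + (m(a)-m(b))^2\\right],

with :math:`h_1, h_2, m` the standardised hydrophobicity, hydrophilicity
and side-chain-mass scales.  The joint normalisation

.. math::

    x_u = \\frac{f_u}{1 + w \\sum_k \\theta_k} \\;(u \\le 20), \\qquad
    x_{20+k} = \\frac{w\\,\\theta_k}{1 + w \\sum_k \\theta_k}

makes every vector non-negative with components summing to exactly 1, so
the descriptor needs no further scaling before model fitting.  Defaults are
:math:`\\lambda = 10` (a 30-dimensional vector) and weight :math:`w = 0.05`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import property_scales
from .dataset import LabeledDataset
from .seqio import STANDARD_AA, ProteinRecord, validate_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropertyTable:
    """Standardised physicochemical scales, as (20,) arrays in alphabetical
    residue order.  Each column has zero mean and unit population SD."""

    hydrophobicity: np.ndarray
    hydrophilicity: np.ndarray
    side_chain_mass: np.ndarray

    @classmethod
    def default(cls) -> "PropertyTable":
        def standardise(values: np.ndarray) -> np.ndarray:
            centred = values - values.mean()
            return centred / np.sqrt(np.mean(centred**2))

        return cls(
            hydrophobicity=standardise(
                property_scales.as_array(property_scales.HYDROPHOBICITY)
            ),
            hydrophilicity=standardise(
                property_scales.as_array(property_scales.HYDROPHILICITY)
            ),
            side_chain_mass=standardise(
                property_scales.as_array(property_scales.SIDE_CHAIN_MASS)
            ),
        )

    def stacked(self) -> np.ndarray:
        return np.stack(
            [self.hydrophobicity, self.hydrophilicity, self.side_chain_mass]
        )


@dataclass(frozen=True)
class PseAACParams:
    """``lam``: maximum correlation lag (default 10, giving 30 components);
    ``weight``: balance of correlation against composition components."""

    lam: int = 10
    weight: float = 0.05

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def n_components(self) -> int:
        return 20 + self.lam


class FeaturizationError(ValueError):
    pass


_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in sequence], dtype=int)
    except KeyError as exc:
        raise FeaturizationError(f"non-standard residue {exc.args[0]!r}") from exc


def theta(sequence: str, k: int, table: PropertyTable | None = None) -> float:
    """Sequence-order correlation factor at lag ``k``.

    Averages the squared property differences of all residue pairs
    ``(i, i+k)``; requires ``len(sequence) >= k + 1``.
    """
    if table is None:
        table = PropertyTable.default()
    if k < 1:
        raise ValueError("lag k must be >= 1")
    if len(sequence) < k + 1:
        raise FeaturizationError(
            f"sequence of length {len(sequence)} too short for lag {k}"
        )
    idx = _encode(sequence)
    scales = table.stacked()  # (3, 20)
    left = scales[:, idx[:-k]]
    right = scales[:, idx[k:]]
    return float(np.mean((left - right) ** 2, axis=0).mean())


def pseaac_vector(
    sequence: str,
    params: PseAACParams | None = None,
    table: PropertyTable | None = None,
) -> np.ndarray:
    """Compute the ``20 + lambda`` PseAAC vector of a sequence.

    Raises :class:`FeaturizationError` for sequences that are too short for
    the requested lag or contain non-standard residues.
    """
    params = params or PseAACParams()
    table = table or PropertyTable.default()
    outcome = validate_sequence(ProteinRecord(id="<seq>", sequence=sequence), params.lam)
    if not outcome.ok:
        raise FeaturizationError(f"{outcome.reason}: {outcome.detail}")
    idx = _encode(sequence)
    freqs = np.bincount(idx, minlength=20) / len(sequence)
    thetas = np.array(
        [theta(sequence, k, table) for k in range(1, params.lam + 1)]
    )
    denom = 1.0 + params.weight * thetas.sum()
    return np.concatenate([freqs / denom, params.weight * thetas / denom])


def feature_names(params: PseAACParams | None = None) -> list[str]:
    """CSV column names: composition by residue, then lagged correlations."""
    params = params or PseAACParams()
    return [f"comp_{a}" for a in STANDARD_AA] + [
        f"theta_{k}" for k in range(1, params.lam + 1)
    ]


def featurize_dataset(
    records: Sequence[ProteinRecord],
    params: PseAACParams | None = None,
    table: PropertyTable | None = None,
    csv_path: str | Path | None = None,
) -> tuple[LabeledDataset, list[tuple[str, str]]]:
    """Featurize records into a labelled 30-column dataset.

    Records failing validation are skipped (and logged) rather than aborting
    the run; the skip list of ``(record id, reason)`` pairs is returned so
    callers can surface it.  Row order follows the input order of passing
    records.  Raises if no record passes.
    """
    params = params or PseAACParams()
    table = table or PropertyTable.default()
    rows: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    skips: list[tuple[str, str]] = []
    for record in records:
        outcome = validate_sequence(record, params.lam)
        if not outcome.ok:
            logger.warning("skipping %s: %s", record.id, outcome.detail)
            skips.append((record.id, outcome.reason or "INVALID"))
            continue
        rows.append(pseaac_vector(record.sequence, params, table))
        labels.append(record.label if record.label is not None else 0)
        ids.append(record.id)
    if not rows:
        raise FeaturizationError("no record passed validation")
    dataset = LabeledDataset(
        features=np.vstack(rows),
        labels=np.array(labels, dtype=int),
        provenance=np.full(len(rows), "real", dtype=object),
        ids=ids,
        feature_names=feature_names(params),
    )
    if csv_path is not None:
        dataset.to_csv(csv_path)
    return dataset, skips
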