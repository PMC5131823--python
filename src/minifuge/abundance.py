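"""EM estimation of species abundance from multi-assigned reads.

Reads from near-identical genomic segments are classified to several species
at once, so unique-read counting underestimates the species involved.  The
generative model: a read comes from species j with probability proportional
to alpha_j * l_j, where alpha_j is the abundance fraction and l_j the average
genome length of species j.  Given the 0/1 read-to-species assignment matrix
C, the likelihood of an abundance vector alpha is

    L(alpha | C) = prod_i  sum_j C_ij * alpha_j * l_j / sum_k alpha_k * l_k.

The maximum-likelihood alpha is found by EM:

* E-step: distribute each read over its assigned species with responsibility
  proportional to alpha_j * l_j, giving expected read counts n_j;
* M-step: alpha'_j = (n_j / l_j) / sum_k (n_k / l_k).

Iteration stops when sum_j |alpha_j - alpha'_j| < 1e-10.  The E-step
responsibilities carry the genome-length weight so that the iteration is a
proper EM for the likelihood above (monotone in log-likelihood, fixed point
at the maximizer); the M-step renormalizes read counts back to genome
fractions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyTree

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


@dataclass
class AssignmentMatrix:
    """Sparse read-by-species incidence with genome lengths.

    Reads sharing an identical assignment pattern are collapsed into one row
    with a multiplicity count; ``patterns[p, j]`` is True when pattern p
    includes species ``species[j]``.
    """

    species: tuple[int, ...]
    lengths: np.ndarray  # average genome length per species, > 0
    patterns: np.ndarray  # bool, shape (P, S)
    pattern_counts: np.ndarray  # int, shape (P,)
    n_dropped: int = 0  # reads whose labels mapped to no database species

    @property
    def n_reads(self) -> int:
        return int(self.pattern_counts.sum())

    @property
    def n_species(self) -> int:
        return len(self.species)

    @classmethod
    def from_label_sets(
        cls,
        label_sets: Iterable[Iterable[int]],
        lengths: Mapping[int, float],
        tree: TaxonomyTree | None = None,
    ) -> "AssignmentMatrix":
        """Build the matrix from per-read label sets.

        ``lengths`` defines the species universe.  Labels above species rank
        are redistributed: the read is assigned to every database species
        below the labeled node.  Strain labels map to their species ancestor.
        Reads whose labels touch no database species are dropped (counted).
        """
        species = tuple(sorted(lengths))
        if not species:
            raise ValueError("no species lengths given")
        lvec = np.array([float(lengths[s]) for s in species], dtype=float)
        if np.any(lvec <= 0):
            raise ValueError("all genome lengths must be positive")
        index = {s: j for j, s in enumerate(species)}

        expand_cache: dict[int, frozenset[int]] = {}

        def to_species(label: int) -> frozenset[int]:
            if label in expand_cache:
                return expand_cache[label]
            out: frozenset[int]
            if label in index:
                out = frozenset((label,))
            elif tree is not None and label in tree:
                anc = tree.ancestor_at_rank(label, "species")
                if anc is not None and anc in index:
                    out = frozenset((anc,))
                else:
                    out = frozenset(
                        t for t in tree.descendants(label) if t in index
                    )
            else:
                out = frozenset()
            expand_cache[label] = out
            return out

        counts: Counter[frozenset[int]] = Counter()
        n_dropped = 0
        for labels in label_sets:
            assigned: set[int] = set()
            for label in labels:
                assigned |= to_species(int(label))
            if assigned:
                counts[frozenset(assigned)] += 1
            else:
                n_dropped += 1
        if not counts:
            raise ValueError("no reads with database-species assignments")
        pats = np.zeros((len(counts), len(species)), dtype=bool)
        cvec = np.empty(len(counts), dtype=np.int64)
        for p, (pattern, c) in enumerate(sorted(counts.items(), key=lambda kv: sorted(kv[0]))):
            for s in pattern:
                pats[p, index[s]] = True
            cvec[p] = c
        return cls(species, lvec, pats, cvec, n_dropped)

    @classmethod
    def from_report(
        cls,
        report: pd.DataFrame,
        lengths: Mapping[int, float],
        tree: TaxonomyTree | None = None,
    ) -> "AssignmentMatrix":
        """Build from a classification report (taxID-0 rows are unclassified)."""
        classified = report[report["taxID"] != 0]
        label_sets = classified.groupby("readID")["taxID"].apply(set).tolist()
        return cls.from_label_sets(label_sets, lengths, tree)


@dataclass
class AbundanceEstimate:
    alpha: dict[int, float]  # abundance fraction per species, sums to 1
    n_hat: dict[int, float]  # expected read count per species, sums to R
    iterations: int
    converged: bool
    log_likelihoods: list[float] | None = None


def _alpha_vector(alpha, matrix: AssignmentMatrix) -> np.ndarray:
    if isinstance(alpha, Mapping):
        vec = np.array([float(alpha[s]) for s in matrix.species], dtype=float)
    else:
        vec = np.asarray(alpha, dtype=float)
    if vec.shape != (matrix.n_species,):
        raise ValueError(
            f"alpha has shape {vec.shape}, expected ({matrix.n_species},)"
        )
    return vec


def log_likelihood(alpha, matrix: AssignmentMatrix) -> float:
    """Log of the assignment likelihood; -inf if some read has zero mass."""
    vec = _alpha_vector(alpha, matrix)
    w = vec * matrix.lengths
    denom = w.sum()
    if denom <= 0:
        return float("-inf")
    mass = matrix.patterns @ w / denom
    if np.any(mass <= 0):
        return float("-inf")
    return float(np.dot(matrix.pattern_counts, np.log(mass)))


def em_estimate(
    matrix: AssignmentMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    track_likelihood: bool = False,
) -> AbundanceEstimate:
    """Maximum-likelihood abundances by EM from uniform initialization."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    if matrix.n_reads == 0 or matrix.n_species == 0:
        raise ValueError("empty assignment matrix")
    S = matrix.n_species
    M = matrix.patterns.astype(float)
    c = matrix.pattern_counts.astype(float)
    lengths = matrix.lengths
    alpha = np.full(S, 1.0 / S)
    trajectory: list[float] | None = [] if track_likelihood else None
    converged = False
    iterations = 0

    def expected_counts(a: np.ndarray) -> np.ndarray:
        w = a * lengths
        denom = M @ w
        safe = np.where(denom > 0, denom, 1.0)
        return w * (M.T @ (c / safe))

    for iterations in range(1, max_iter + 1):
        n = expected_counts(alpha)
        unnorm = n / lengths
        total = unnorm.sum()
        if total <= 0:
            raise RuntimeError("EM degenerated to zero mass")
        alpha_new = unnorm / total
        delta = float(np.abs(alpha - alpha_new).sum())
        alpha = alpha_new
        if trajectory is not None:
            trajectory.append(log_likelihood(alpha, matrix))
        if delta < tol:
            converged = True
            break

    n_final = expected_counts(alpha)
    return AbundanceEstimate(
        alpha={s: float(a) for s, a in zip(matrix.species, alpha)},
        n_hat={s: float(v) for s, v in zip(matrix.species, n_final)},
        iterations=iterations,
        converged=converged,
        log_likelihoods=trajectory,
    )


def unique_normalized_counts(
    report_or_label_sets,
    lengths: Mapping[int, float],
) -> dict[int, float]:
    """Unique read counts per species, divided by genome length and rescaled
    to fractions of the maximum (the heat-map normalization).

    Accepts either a classification report frame or an iterable of per-read
    label sets.
    """
    counts: Counter[int] = Counter()
    if isinstance(report_or_label_sets, pd.DataFrame):
        frame = report_or_label_sets
        unique_rows = frame[(frame["numMatches"] == 1) & (frame["taxID"] != 0)]
        for taxid in unique_rows["taxID"]:
            if taxid in lengths:
                counts[int(taxid)] += 1
    else:
        for labels in report_or_label_sets:
            labels = list(labels)
            if len(labels) == 1 and labels[0] in lengths:
                counts[int(labels[0])] += 1
    values = {s: counts.get(s, 0) / float(lengths[s]) for s in lengths}
    peak = max(values.values(), default=0.0)
    if peak <= 0:
        return {s: 0.0 for s in lengths}
    return {s: v / peak for s, v in values.items()}


def aggregate_rank(
    estimate: AbundanceEstimate, tree: TaxonomyTree, rank: str
) -> dict[int | str, float]:
    """Sum species abundances by rank ancestor; missing ancestors pool under
    ``"unassigned"``.  The output still sums to 1."""
    out: dict[int | str, float] = {}
    for species, a in estimate.alpha.items():
        anc: int | str | None = (
            tree.ancestor_at_rank(species, rank) if species in tree else None
        )
        key: int | str = anc if anc is not None else "unassigned"
        out[key] = out.get(key, 0.0) + a
    return out
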