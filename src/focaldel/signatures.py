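"""Mutation catalogs and signature refitting with forward selection.

A catalog is a vector of mutation counts over fixed channels (the 96
trinucleotide substitution classes for SBS, or pre-built indel/SV
channels). Refitting expresses a catalog as a non-negative linear
combination of reference signature probability vectors via NNLS. The
active set is chosen greedily: signatures are added one at a time, each
iteration admitting the candidate whose inclusion most improves the
cosine similarity between reconstruction and catalog, and stopping when
no candidate improves it by more than a margin (0.001 by default) — so
every retained signature pays for itself in reconstruction quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

BASES = "ACGT"
PYRIMIDINE_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def sbs96_labels() -> list[str]:
    """The 96 SBS channel labels in COSMIC order, e.g. 'A[C>A]A'."""
    return [f"{five}[{sub}]{three}"
            for sub in PYRIMIDINE_SUBS for five in BASES for three in BASES]


SBS96_LABELS = sbs96_labels()


@dataclass
class MutationCatalog:
    labels: list[str]
    counts: np.ndarray
    channel_set: str = "custom"  # SBS96 | ID83 | SV | custom

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.labels)


@dataclass
class RefitResult:
    selected: list[str]
    weights: pd.Series  # attributed mutation counts, >= 0
    reconstruction: np.ndarray
    cosine_similarity: float
    trace: list[dict] = field(default_factory=list)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def count_sbs96(snvs: pd.DataFrame) -> MutationCatalog:
    """Build an SBS96 catalog from SNVs with +-1 bp reference context.

    ``snvs`` needs columns ``ref``, ``alt`` and ``context`` (the 3-mer
    centered on the variant). Mutations from a purine reference are
    mapped to the pyrimidine strand by reverse complement, the standard
    convention that folds the 192 stranded classes to 96.
    """
    counts = dict.fromkeys(SBS96_LABELS, 0)
    for row in snvs.itertuples():
        ref, alt, ctx = str(row.ref).upper(), str(row.alt).upper(), str(row.context).upper()
        if len(ctx) != 3 or ctx[1] != ref:
            raise ValueError(f"context {ctx!r} does not match ref {ref!r}")
        if ref not in BASES or alt not in BASES or ref == alt:
            raise ValueError(f"invalid substitution {ref}>{alt}")
        if ref in "GA":  # purine reference: flip to the pyrimidine strand
            ctx = _revcomp(ctx)
            ref, alt = _revcomp(ref), _revcomp(alt)
        label = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
        counts[label] += 1
    return MutationCatalog(SBS96_LABELS, np.array([counts[k] for k in SBS96_LABELS]),
                           channel_set="SBS96")


def _check_library(catalog: MutationCatalog, library: pd.DataFrame) -> pd.DataFrame:
    if catalog.total <= 0:
        raise ValueError("cannot refit a zero catalog")
    lib = library.reindex(index=catalog.labels)
    if lib.isna().any().any():
        raise ValueError("signature matrix missing catalog channels")
    colsums = lib.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("signature columns must sum to 1 (probability vectors)")
    return lib


def refit_nnls(catalog: MutationCatalog, library: pd.DataFrame) -> tuple[pd.Series, float]:
    """Non-negative least squares of the count vector on signature columns.

    Returns the weights (attributed mutation counts) and the cosine
    similarity between reconstruction and catalog.
    """
    lib = _check_library(catalog, library)
    w, _ = nnls(lib.to_numpy(), catalog.counts)
    weights = pd.Series(w, index=lib.columns)
    recon = lib.to_numpy() @ w
    return weights, cosine_similarity(recon, catalog.counts)


class SignatureRefitter(BaseEstimator):
    """Greedy forward selection of reference signatures by cosine gain.

    Parameters
    ----------
    signatures : DataFrame
        COSMIC-layout matrix, channel rows x signature columns, columns
        summing to 1.
    margin : float
        Minimum cosine-similarity improvement a candidate must deliver to
        be admitted (default 0.001).

    Attributes (after fit)
    ----------------------
    selected_ : list of admitted signature names, in admission order
    weights_ : Series of attributed mutation counts on the selected set
    cosine_similarity_ : float
    trace_ : list of per-iteration records (candidate, cosine, gain)
    """

    def __init__(self, signatures: pd.DataFrame = None, margin: float = 0.001):
        self.signatures = signatures
        self.margin = margin

    def fit(self, X, y=None):
        catalog = X if isinstance(X, MutationCatalog) else MutationCatalog(
            list(self.signatures.index), np.asarray(X, dtype=float))
        lib = _check_library(catalog, self.signatures)

        selected: list[str] = []
        trace: list[dict] = []
        current_cos = 0.0
        remaining = list(lib.columns)
        while remaining:
            best_name, best_cos = None, current_cos
            for name in remaining:
                _, cos = refit_nnls(catalog, lib[selected + [name]])
                if cos > best_cos:
                    best_name, best_cos = name, cos
            gain = best_cos - current_cos
            if best_name is None or gain <= self.margin:
                break
            selected.append(best_name)
            remaining.remove(best_name)
            trace.append({"iteration": len(selected), "candidate": best_name,
                          "cosine": best_cos, "gain": gain})
            current_cos = best_cos

        if selected:
            weights, cos = refit_nnls(catalog, lib[selected])
            recon = lib[selected].to_numpy() @ weights.to_numpy()
        else:
            weights = pd.Series(dtype=float)
            cos = 0.0
            recon = np.zeros_like(catalog.counts)
        self.selected_ = selected
        self.weights_ = weights
        self.cosine_similarity_ = float(cos)
        self.reconstruction_ = recon
        self.trace_ = trace
        return self

    def result_(self) -> RefitResult:
        check_is_fitted(self, "selected_")
        return RefitResult(selected=list(self.selected_), weights=self.weights_,
                           reconstruction=self.reconstruction_,
                           cosine_similarity=self.cosine_similarity_,
                           trace=list(self.trace_))


def forward_select(catalog: MutationCatalog, library: pd.DataFrame,
                   margin: float = 0.001) -> RefitResult:
    """Iterative signature selection; wrapper over SignatureRefitter."""
    return SignatureRefitter(signatures=library, margin=margin).fit(catalog).result_()
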