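"""Synthetic cohorts and image fixtures.

Generates two-group cohorts of multivariate-Gaussian ROI volumes by
ancestral sampling from group-specific linear-Gaussian networks.  The
default specification mirrors the published young/old default-mode-network
models: each group's DAG and edge coefficients are the reported connection
lists and weight coefficients, group sizes are 109 ("young") and 82
("old"), sexes are Bernoulli with the reported group frequencies and ages
uniform within the reported ranges.  Residual variances default to
``1 - explained variance`` so every node has unit marginal variance on the
standardized scale, and samples are mapped to a plausible gray-matter
probability scale (mean 0.5, sd 0.05 per ROI) before being written as
cohort volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import LinearGaussianBN, LinearGaussianCPD, Standardization
from .cohort import DEFAULT_ROI_NAMES, CohortTable, RoiSpec
from .dag import DAG
from .volumes import GmImage, RoiMask

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "YOUNG_EDGES",
    "OLD_EDGES",
    "default_spec",
    "make_group_model",
    "make_cohort",
    "make_nifti_fixture",
]

#: Young-group generator: 9 directed edges with their reported standardized
#: weight coefficients.
YOUNG_EDGES: dict[tuple[str, str], float] = {
    ("lHP", "mPFC"): 0.284,
    ("rITC", "lITC"): 0.784,
    ("rITC", "mPFC"): 0.469,
    ("rHP", "rITC"): 0.576,
    ("PCC", "lIPC"): 0.422,
    ("mPFC", "PCC"): 0.548,
    ("mPFC", "lIPC"): 0.292,
    ("rHP", "lHP"): 0.921,
    ("lIPC", "rIPC"): 0.625,
}

#: Old-group generator: 8 directed edges.  Relative to the young structure
#: the shared edges are lHP->mPFC, rITC->lITC and rITC->mPFC; lITC->lHP,
#: rIPC->rITC and PCC->rIPC are old-only; the inter-hemispheric hippocampal
#: and parietal edges are reversed in orientation.
OLD_EDGES: dict[tuple[str, str], float] = {
    ("lHP", "mPFC"): 0.292,
    ("rITC", "lITC"): 0.723,
    ("rITC", "mPFC"): 0.372,
    ("lITC", "lHP"): 0.425,
    ("rIPC", "rITC"): 0.559,
    ("PCC", "rIPC"): 0.576,
    ("lHP", "rHP"): 0.773,
    ("rIPC", "lIPC"): 0.649,
}


@dataclass(frozen=True)
class GroupSpec:
    """Generator settings for one group.

    edges maps (parent, child) to the structural coefficient on the
    standardized scale.  ``residual_variances`` overrides the default
    1 - explained-variance rule per node.  ``means``/``sds`` de-standardize
    samples onto the volume scale (scalar or one value per ROI).
    """

    label: str
    n: int
    edges: Mapping[tuple[str, str], float] = field(default_factory=dict)
    residual_variances: Mapping[str, float] = field(default_factory=dict)
    means: float | Sequence[float] = 0.5
    sds: float | Sequence[float] = 0.05
    female_prob: float = 0.5
    age_range: tuple[float, float] = (20.0, 90.0)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not all(np.isfinite(list(self.edges.values()) or [0.0])):
            raise ValueError("edge coefficients must be finite")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full two-group cohort specification (ROI names, group specs, seed)."""

    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    groups: tuple[GroupSpec, ...] = ()
    seed: int | None = None


def default_spec(seed: int | None = None, n_young: int = 109, n_old: int = 82) -> SyntheticSpec:
    """The study-conditions spec: published structures/weights and group
    sizes, reported sex frequencies, ages uniform in the reported ranges."""
    young = GroupSpec(
        label="young",
        n=n_young,
        edges=YOUNG_EDGES,
        female_prob=65 / 109,
        age_range=(20.0, 28.0),
    )
    old = GroupSpec(
        label="old",
        n=n_old,
        edges=OLD_EDGES,
        female_prob=60 / 82,
        age_range=(60.0, 90.0),
    )
    return SyntheticSpec(groups=(young, old), seed=seed)


def make_group_model(
    spec: GroupSpec, roi_names: Sequence[str] | None = None
) -> LinearGaussianBN:
    """Build the generating network for one group.

    Residual variances default to 1 minus the variance the parents explain
    (so each node is marginally standard normal); a non-positive implied
    variance raises with a hint to rescale the coefficients.  The returned
    network stores the de-standardization (means, sds), so ``sample(...,
    raw=True)`` and raw-scale ``logpdf`` work directly.
    """
    roi_names = tuple(roi_names) if roi_names is not None else DEFAULT_ROI_NAMES
    dag = DAG(roi_names, spec.edges.keys())
    idx = {n_: i for i, n_ in enumerate(roi_names)}
    d = len(roi_names)
    Sigma = np.zeros((d, d))
    cpds = {}
    for node in dag.topological_order():
        parents = dag.parents(node)
        beta = np.array([spec.edges[(p, node)] for p in parents])
        j = idx[node]
        if parents:
            pj = [idx[p] for p in parents]
            explained = float(beta @ Sigma[np.ix_(pj, pj)] @ beta)
            resid = spec.residual_variances.get(node, 1.0 - explained)
            if resid <= 0:
                raise ValueError(
                    f"node {node!r}: implied residual variance {resid:.3f} <= 0; "
                    "rescale the edge coefficients"
                )
            Sigma[j, :] = beta @ Sigma[pj, :]
            Sigma[:, j] = Sigma[j, :]
            Sigma[j, j] = explained + resid
        else:
            resid = spec.residual_variances.get(node, 1.0)
            Sigma[j, j] = resid
        cpds[node] = LinearGaussianCPD(
            node=node,
            parents=parents,
            intercept=0.0,
            coefficients=beta,
            residual_variance=float(resid),
        )
    means = np.broadcast_to(np.asarray(spec.means, float), (d,)).copy()
    sds = np.broadcast_to(np.asarray(spec.sds, float), (d,)).copy()
    return LinearGaussianBN(
        dag, cpds, standardization=Standardization(means, sds), n=None
    )


def make_cohort(spec: SyntheticSpec) -> CohortTable:
    """Sample a full cohort table from a :class:`SyntheticSpec`.

    Per group: ancestral-sample the group model, de-standardize onto the
    volume scale, attach sampled sex and age, and concatenate.  One integer
    seed makes the whole table reproducible (per-group streams are spawned
    from it, so group outputs do not interleave).
    """
    if not spec.groups:
        raise ValueError("spec has no groups")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(spec.groups))
    frames = []
    for gspec, child in zip(spec.groups, children):
        rng = np.random.default_rng(child)
        model = make_group_model(gspec, spec.roi_names)
        vols = model.sample(gspec.n, seed=rng, raw=True)
        sex = np.where(rng.random(gspec.n) < gspec.female_prob, "F", "M")
        lo, hi = gspec.age_range
        age = np.round(rng.uniform(lo, hi, size=gspec.n), 1)
        df = pd.DataFrame(
            {
                "subject_id": [f"{gspec.label}_{i:04d}" for i in range(gspec.n)],
                "group": gspec.label,
                "sex": sex,
                "age": age,
            }
        )
        df[list(spec.roi_names)] = vols
        frames.append(df)
    return CohortTable(pd.concat(frames, ignore_index=True), spec.roi_names)


def make_nifti_fixture(
    rois: Sequence[RoiSpec],
    intensities: np.ndarray,
    subject_ids: Sequence[str] | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    block: int = 3,
    speckle: float = 0.0,
    seed: int | None = None,
) -> tuple[dict[str, GmImage], RoiMask]:
    """Tiny in-memory image fixture: one constant rectangular block per ROI.

    *intensities* is (n_subjects, n_rois); each subject's image holds the
    requested value throughout the corresponding ROI block, so the masked
    thresholded mean recovers it exactly.  *speckle* (must stay at or below
    the extraction cut-off to be inert) fills the background.  Blocks are
    laid out disjointly along the first axis; a too-small grid raises.
    """
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    n_sub, n_roi = intensities.shape
    if n_roi != len(rois):
        raise ValueError("one intensity column per ROI required")
    if subject_ids is None:
        subject_ids = [f"sub_{i:03d}" for i in range(n_sub)]
    stride = block + 1
    need = n_roi * stride
    if grid_shape is None:
        grid_shape = (need, block + 2, block + 2)
    if grid_shape[0] < need or grid_shape[1] < block or grid_shape[2] < block:
        raise ValueError(
            f"grid {grid_shape} too small for {n_roi} disjoint {block}^3 blocks"
        )
    labels = np.zeros(grid_shape, dtype=int)
    slices = []
    for k, roi in enumerate(rois):
        sl = (
            slice(k * stride, k * stride + block),
            slice(0, block),
            slice(0, block),
        )
        if np.any(labels[sl] != 0):
            raise ValueError("overlapping ROI blocks")
        labels[sl] = roi.atlas_labels[0]
        slices.append(sl)
    mask = RoiMask(labels)
    rng = np.random.default_rng(seed)
    images = {}
    for i, sid in enumerate(subject_ids):
        data = np.full(grid_shape, float(speckle))
        if speckle > 0:
            data *= rng.uniform(0.5, 1.0, size=grid_shape)
        for k in range(n_roi):
            data[slices[k]] = intensities[i, k]
        images[sid] = GmImage(data)
    return images, mask
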