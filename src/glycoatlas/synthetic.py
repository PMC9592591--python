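"""Synthetic glycome-atlas generation.

Generates atlas-like datasets with the structure of a mouse tissue
N-glycome study — a library of biosynthetically valid compositions, an
18-class x 5-replicate x 103-glycoform abundance matrix spanning about
four decades (emulating 0.04–903 pmol / 100 ug protein) with
class-specific marker glycoforms and detection dropout, and
strain-perturbed variants of a single class — so every pipeline stage
can be exercised, with known ground truth, without the original data.

Abundances are log-normal: per-glycoform baseline means are drawn on a
log10 scale shared across classes, class markers are shifted by a
multiplicative fold change, and replicates add mean-preserving
multiplicative noise of a configured CV.  Values below the detection
limit are masked as not detected (deterministic thresholding, matching
the grey-cell semantics of atlas heatmaps); an optional random-dropout
rate adds stochastic misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CompositionBounds, DEFAULT_BOUNDS, Peak, PeakList, is_plausible
from .core import DerivatizationModel, GlycanComposition, derivatized_mz
from .glycotyping import GLYCAN_TYPES, classify_type
from .quantification import ProfileMatrix

__all__ = [
    "SyntheticAtlasSpec",
    "generate_library",
    "generate_atlas",
    "generate_strain_variants",
    "emit_peaklists",
    "DEFAULT_CLASS_NAMES",
]

# Organ/tissue/fluid panel of a full-body mouse atlas (16 organs,
# serum, serum-derived exosomes).
DEFAULT_CLASS_NAMES = (
    "brain", "femur", "heart", "intestine", "kidney", "liver", "lung",
    "muscle", "ovary", "pancreas", "skin", "spleen", "stomach", "testis",
    "thyroid", "uterus", "serum", "exosome",
)


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    """Study-design parameters of a synthetic atlas.

    Defaults mirror the full-body design: 18 sample classes x 5
    replicates over a 103-glycoform library, log-normal abundances
    whose detected values span roughly four orders of magnitude above a
    0.04 pmol detection limit, 8 marker glycoforms per class at a
    20-fold shift, and 25% multiplicative replicate noise.
    """

    n_classes: int = 18
    replicates: int = 5
    library_size: int = 103
    marker_count: int = 8
    marker_fold: float = 20.0
    baseline_log10_mean: float = -2.0
    baseline_log10_sd: float = 1.5
    replicate_cv: float = 0.25
    detection_limit: float = 0.04
    random_dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.replicates, self.library_size) < 1:
            raise ValueError("counts must be positive")
        if self.marker_count < 0 or self.marker_count > self.library_size:
            raise ValueError("marker_count must be in [0, library_size]")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if not 0 <= self.random_dropout_rate < 1:
            raise ValueError("random_dropout_rate must be in [0, 1)")


def generate_library(
    size: int,
    seed: int = 0,
    bounds: CompositionBounds = DEFAULT_BOUNDS,
    min_mass_separation: float = 0.5,
) -> list[GlycanComposition]:
    """Sample *size* unique, biosynthetically valid compositions.

    All compositions pass the annotation plausibility constraints; when
    *size* allows, every glycan type (paucimannose, high-mannose,
    hybrid, complex) is represented.  Entries are kept at least
    *min_mass_separation* Da apart in derivatized m/z, mirroring a real
    peak-derived library where each entry is a distinct observed peak
    (the composition grid contains strictly isobaric pairs such as
    Hex+Neu5Ac vs dHex+Neu5Gc, which a single MALDI peak cannot
    separate).  Deterministic per seed.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    pool = [c for c in bounds.iter_compositions() if is_plausible(c)]
    rng = np.random.default_rng(seed)
    model = DerivatizationModel()
    mass_of = {c: derivatized_mz(c, model) for c in pool}

    chosen: list[GlycanComposition] = []
    masses: list[float] = []

    def try_add(comp: GlycanComposition) -> bool:
        mz = mass_of[comp]
        if any(abs(mz - m) < min_mass_separation for m in masses):
            return False
        chosen.append(comp)
        masses.append(mz)
        return True

    if size >= len(GLYCAN_TYPES):
        # one representative per type first, so all four are present
        by_type: dict[str, list[GlycanComposition]] = {t: [] for t in GLYCAN_TYPES}
        for comp in pool:
            by_type[classify_type(comp)].append(comp)
        for t in GLYCAN_TYPES:
            members = by_type[t]
            for i in rng.permutation(len(members)):
                if try_add(members[i]):
                    break

    chosen_set = set(chosen)
    remaining = [c for c in pool if c not in chosen_set]
    for i in rng.permutation(len(remaining)):
        if len(chosen) == size:
            break
        try_add(remaining[i])
    if len(chosen) < size:
        raise ValueError(
            f"requested {size} compositions but only {len(chosen)} fit the bounds "
            f"at {min_mass_separation} Da mass separation"
        )
    chosen.sort(key=lambda c: (c.total_residues, str(c)))
    return chosen


def _replicate_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-preserving multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=shape)


def generate_atlas(
    spec: SyntheticAtlasSpec,
    class_names: tuple[str, ...] | None = None,
) -> tuple[ProfileMatrix, dict]:
    """Generate a class-structured abundance matrix plus ground truth.

    Returns the profile matrix (amounts in pmol / 100 ug protein, with
    sub-detection-limit cells zeroed and masked) and a ground-truth
    record holding the library, per-glycoform baseline means, per-class
    marker identities and the noiseless class-mean matrix.
    """
    rng = np.random.default_rng(spec.seed)
    library = generate_library(spec.library_size, seed=spec.seed)
    comps = [str(c) for c in library]

    if class_names is None:
        if spec.n_classes <= len(DEFAULT_CLASS_NAMES):
            class_names = DEFAULT_CLASS_NAMES[: spec.n_classes]
        else:
            class_names = tuple(f"class{i + 1:02d}" for i in range(spec.n_classes))
    elif len(class_names) != spec.n_classes:
        raise ValueError("class_names length must equal n_classes")

    baseline = 10.0 ** rng.normal(
        spec.baseline_log10_mean, spec.baseline_log10_sd, spec.library_size
    )
    markers: dict[str, list[str]] = {}
    class_means = np.tile(baseline, (spec.n_classes, 1))
    for ci, cls in enumerate(class_names):
        midx = rng.choice(spec.library_size, size=spec.marker_count, replace=False)
        markers[cls] = [comps[i] for i in sorted(midx)]
        class_means[ci, midx] *= spec.marker_fold

    rows, sample_ids, labels, reps = [], [], [], []
    for ci, cls in enumerate(class_names):
        noise = _replicate_noise(
            rng, spec.replicate_cv, (spec.replicates, spec.library_size)
        )
        block = class_means[ci] * noise
        for r in range(spec.replicates):
            rows.append(block[r])
            sample_ids.append(f"{cls}_{r + 1}")
            labels.append(cls)
            reps.append(r + 1)

    values = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=comps)
    mask = values >= spec.detection_limit
    if spec.random_dropout_rate > 0:
        keep = rng.random(values.shape) >= spec.random_dropout_rate
        mask &= keep
    values = values.where(mask, 0.0)
    samples = pd.DataFrame(
        {"class_label": labels, "replicate": reps}, index=pd.Index(sample_ids)
    )
    truth = {
        "library": library,
        "baseline_means": pd.Series(baseline, index=comps),
        "markers": markers,
        "class_means": pd.DataFrame(
            class_means, index=list(class_names), columns=comps
        ),
        "spec": spec,
    }
    return ProfileMatrix(values, mask, samples), truth


def generate_strain_variants(
    base_profile: pd.Series,
    effect_size: float = 5.0,
    n_affected: int = 10,
    n_strains: int = 3,
    replicates: int = 5,
    replicate_cv: float = 0.25,
    detection_limit: float = 0.04,
    seed: int = 0,
    strain_names: tuple[str, ...] | None = None,
) -> tuple[ProfileMatrix, dict]:
    """Strain-perturbed replicates of one class profile.

    The first strain is the unperturbed reference; each further strain
    multiplies a random glycoform subset of size *n_affected* by
    *effect_size*.  Emulates a multi-strain single-organ comparison
    (e.g. lungs of an outbred reference, an inbred strain and a disease
    model).
    """
    if n_affected > len(base_profile):
        raise ValueError("n_affected exceeds the library size")
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    comps = list(base_profile.index)
    if strain_names is None:
        strain_names = tuple(f"strain{chr(ord('A') + i)}" for i in range(n_strains))
    elif len(strain_names) != n_strains:
        raise ValueError("strain_names length must equal n_strains")

    affected: dict[str, list[str]] = {strain_names[0]: []}
    strain_means = [base_profile.to_numpy(dtype=float)]
    for name in strain_names[1:]:
        idx = rng.choice(len(comps), size=n_affected, replace=False)
        affected[name] = [comps[i] for i in sorted(idx)]
        mean = base_profile.to_numpy(dtype=float).copy()
        mean[idx] *= effect_size
        strain_means.append(mean)

    rows, sample_ids, labels, reps = [], [], [], []
    for name, mean in zip(strain_names, strain_means):
        noise = _replicate_noise(rng, replicate_cv, (replicates, len(comps)))
        block = mean * noise
        for r in range(replicates):
            rows.append(block[r])
            sample_ids.append(f"{name}_{r + 1}")
            labels.append(name)
            reps.append(r + 1)
    values = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=comps)
    mask = values >= detection_limit
    values = values.where(mask, 0.0)
    samples = pd.DataFrame(
        {"class_label": labels, "replicate": reps}, index=pd.Index(sample_ids)
    )
    truth = {"affected": affected, "strain_names": strain_names}
    return ProfileMatrix(values, mask, samples), truth


def emit_peaklists(
    matrix: ProfileMatrix,
    model: DerivatizationModel = DerivatizationModel(),
    is_amount: float = 10.0,
    is_area: float = 1000.0,
    is_mz: float = 2446.85,
) -> list[PeakList]:
    """Invert quantitation: render a profile matrix as synthetic peak lists.

    Each detected glycoform becomes a peak at its derivatized m/z with
    area = amount / is_amount * is_area, so quantifying the emitted
    peak lists against the internal standard (at *is_mz*, *is_area*)
    reproduces the matrix exactly.  Used for end-to-end round-trip
    tests.
    """
    from .core import parse_composition

    mz_of = {
        comp: derivatized_mz(parse_composition(comp), model)
        for comp in matrix.values.columns
    }
    out: list[PeakList] = []
    for sample_id, row in matrix.values.iterrows():
        detected = matrix.mask.loc[sample_id]
        peaks = [
            Peak(mz_of[comp], amount / is_amount * is_area)
            for comp, amount in row.items()
            if detected[comp]
        ]
        meta = matrix.samples.loc[sample_id]
        out.append(
            PeakList(
                sample_id=str(sample_id),
                class_label=str(meta["class_label"]),
                replicate=int(meta["replicate"]),
                peaks=peaks,
                internal_standard=Peak(is_mz, is_area),
            )
        )
    return out
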