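"""Ensemble runs, dual variance estimates, flags, and probability binning.

Three network configurations (FPHW 9:3:2, FP 6:3:2, HW 3:3:2) are each run
through repeated leave-one-out train-test cycles with fresh random weight
initializations. Two variances summarize the stochastic spread:

* V_RA (intra-network): sample variance of one configuration's P_tumor
  across the cycles — how sure that configuration is of its own answer.
* V_ER (inter-network): sample variance across the three configurations'
  mean P_tumor values — how much the configurations disagree.

Both use denominator n-1 (the convention is recorded in report metadata).
Targets whose variance exceeds its family mean by more than one family
standard deviation are flagged. The maximum of the three mean
probabilities drives the equal-width probability quintile bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .features import FeatureMatrix
from .neural import LabeledFeatures, NetworkConfig, loo_round_robin

CONFIG_TAGS = ("FPHW", "FP", "HW")


@dataclass
class ProbabilityRecord:
    """One target x one configuration: cycle probabilities and V_RA."""

    target_id: str
    config_tag: str
    cycle_probs: np.ndarray
    mean_prob: float = field(init=False)
    V_RA: float = field(init=False)

    def __post_init__(self) -> None:
        self.cycle_probs = np.asarray(self.cycle_probs, dtype=float)
        if self.cycle_probs.ndim != 1 or len(self.cycle_probs) < 2:
            raise ValidationError("cycle_probs must be 1-D with >= 2 cycles")
        if ((self.cycle_probs < 0) | (self.cycle_probs > 1)).any():
            raise ValidationError("cycle probabilities must lie in [0, 1]")
        self.mean_prob = float(self.cycle_probs.mean())
        self.V_RA = float(np.var(self.cycle_probs, ddof=1))


@dataclass
class EnsembleRecord:
    """Per-target ensemble summary across the three configurations."""

    target_id: str
    mean_probs: dict[str, float]
    v_ra: dict[str, float]
    V_ER: float
    max_prob: float
    quintile_bin: int
    flag_VRA: dict[str, bool] = field(default_factory=dict)
    flag_VER: bool = False


@dataclass
class FlagThresholds:
    """1-sigma flag thresholds (family mean + 1 family std) per family."""

    sigma_VRA: dict[str, float]
    sigma_VER: float
    method: str = "family mean + 1 sample std (ddof=1); flag when value > threshold"


def bin_quintile(max_prob: float) -> int:
    """Equal-width probability bin 1-5.

    Edges: [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1.0]; the last
    bin is closed at 1.0.
    """
    p = float(max_prob)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability {p} outside [0, 1]")
    return min(int(np.floor(p * 5.0)) + 1, 5)


def run_ensemble(
    features_by_set: Mapping[str, FeatureMatrix],
    labels: LabeledFeatures | Mapping[str, LabeledFeatures],
    n_cycles: int = 10,
    base_seed: int = 0,
    max_epochs: int = 1000,
    grad_tol: float = 1e-6,
    n_hidden: int = 3,
    train_mask: np.ndarray | None = None,
) -> list[ProbabilityRecord]:
    """Run all three configurations through ``n_cycles`` LOO cycles each.

    ``labels`` may be a single LabeledFeatures (shared one-hot targets,
    e.g. histology) or a mapping tag -> LabeledFeatures (per-set k-means
    labels). Weight-init seeds follow the documented schedule with
    effective base seed ``base_seed*10 + config_index``.
    """
    if n_cycles < 2:
        raise ValidationError("n_cycles must be >= 2")
    missing = [t for t in CONFIG_TAGS if t not in features_by_set]
    if missing:
        raise ValidationError(f"missing feature sets: {missing}")
    ids0 = features_by_set["FPHW"].target_ids
    for tag in CONFIG_TAGS:
        if features_by_set[tag].target_ids != ids0:
            raise ValidationError(
                f"feature set {tag} target order differs from FPHW"
            )
    records: list[ProbabilityRecord] = []
    for ci, tag in enumerate(CONFIG_TAGS):
        fm = features_by_set[tag]
        if isinstance(labels, LabeledFeatures):
            lab = LabeledFeatures(fm, labels.targets, labels.gold_standard_source)
        else:
            lab = labels[tag]
            if lab.features.target_ids != ids0:
                raise ValidationError(f"labels for {tag} have mismatched order")
        config = NetworkConfig(
            n_inputs=fm.n_bands,
            n_hidden=n_hidden,
            max_epochs=max_epochs,
            grad_tol=grad_tol,
            seed=base_seed * 10 + ci,
        )
        cycle_matrix = np.empty((n_cycles, fm.n_targets))
        for c in range(n_cycles):
            cycle_matrix[c] = loo_round_robin(
                lab, config, cycle_index=c, train_mask=train_mask
            )
        for j, tid in enumerate(ids0):
            records.append(
                ProbabilityRecord(
                    target_id=tid, config_tag=tag, cycle_probs=cycle_matrix[:, j]
                )
            )
    return records


def ensemble_variance(records: Sequence[ProbabilityRecord]) -> EnsembleRecord:
    """Combine one target's three per-configuration records."""
    if len(records) != 3:
        raise ValidationError("exactly one record per configuration required")
    tags = {r.config_tag for r in records}
    if tags != set(CONFIG_TAGS):
        raise ValidationError(f"need one record per {CONFIG_TAGS}, got {sorted(tags)}")
    tids = {r.target_id for r in records}
    if len(tids) != 1:
        raise ValidationError("records belong to different targets")
    by_tag = {r.config_tag: r for r in records}
    means = {t: by_tag[t].mean_prob for t in CONFIG_TAGS}
    vals = np.array([means[t] for t in CONFIG_TAGS])
    v_er = float(np.var(vals, ddof=1))
    max_prob = float(vals.max())
    return EnsembleRecord(
        target_id=records[0].target_id,
        mean_probs=means,
        v_ra={t: by_tag[t].V_RA for t in CONFIG_TAGS},
        V_ER=v_er,
        max_prob=max_prob,
        quintile_bin=bin_quintile(max_prob),
    )


def build_ensemble_records(
    prob_records: Sequence[ProbabilityRecord],
) -> list[EnsembleRecord]:
    """Group probability records by target (dataset order preserved)."""
    order: list[str] = []
    grouped: dict[str, list[ProbabilityRecord]] = {}
    for r in prob_records:
        if r.target_id not in grouped:
            grouped[r.target_id] = []
            order.append(r.target_id)
        grouped[r.target_id].append(r)
    return [ensemble_variance(grouped[tid]) for tid in order]


def compute_flags(
    ensemble_records: Sequence[EnsembleRecord],
    method: str = "mean_plus_sigma",
) -> FlagThresholds:
    """Apply 1-sigma flags in place and return the thresholds used.

    For each variance family (V_RA of each configuration; V_ER) the
    threshold is the family mean plus one sample standard deviation over
    all targets; values strictly above it are flagged. A family with zero
    spread flags nothing. Flags are invariant to target order and to a
    global rescaling of a family.
    """
    if method != "mean_plus_sigma":
        raise ValidationError(f"unknown flag method {method!r}")
    records = list(ensemble_records)
    if len(records) < 3:
        raise ValidationError("flagging needs at least 3 targets")
    thresholds_vra: dict[str, float] = {}
    for tag in CONFIG_TAGS:
        fam = np.array([r.v_ra[tag] for r in records])
        thr = float(fam.mean() + fam.std(ddof=1))
        thresholds_vra[tag] = thr
        for r in records:
            r.flag_VRA[tag] = bool(r.v_ra[tag] > thr)
    fam_er = np.array([r.V_ER for r in records])
    thr_er = float(fam_er.mean() + fam_er.std(ddof=1))
    for r in records:
        r.flag_VER = bool(r.V_ER > thr_er)
    return FlagThresholds(sigma_VRA=thresholds_vra, sigma_VER=thr_er)


@dataclass
class BoundaryFit:
    """Degree-5 fit of V_RA against mean P_tumor and its 1-sigma crossings."""

    coefficients: np.ndarray  # power basis, ascending
    sigma_level: float
    crossings: np.ndarray


def fit_boundary_poly(
    mean_probs: Sequence[float],
    v_ra: Sequence[float],
    degree: int = 5,
    sigma_level: float | None = None,
) -> BoundaryFit:
    """Least-squares polynomial of V_RA vs mean P_tumor; boundary-zone edges.

    The real roots of (fit - sigma_level) inside [0, 1] mark where the
    intra-network variance rises above the 1-sigma level — the boundary
    zone between confidently-healthy and confidently-tumor predictions.
    Reporting aid only; classification never consumes it.
    """
    p = np.asarray(mean_probs, dtype=float)
    v = np.asarray(v_ra, dtype=float)
    if p.shape != v.shape or p.ndim != 1:
        raise ValidationError("mean_probs and v_ra must be equal-length 1-D")
    if len(p) < degree + 2:
        raise ValidationError(f"need at least {degree + 2} points for degree {degree}")
    if np.ptp(p) == 0:
        raise ValidationError("degenerate design: all mean probabilities equal")
    if sigma_level is None:
        sigma_level = float(v.mean() + v.std(ddof=1))
    # unscaled power-basis fit; mean_probs live in [0,1] so conditioning is
    # acceptable, and near-degenerate designs (e.g. variances all ~0) are
    # handled explicitly below rather than through numpy's rank warning
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeffs = np.polynomial.polynomial.polyfit(p, v, degree)
    shifted = coeffs.copy()
    shifted[0] -= sigma_level
    if sigma_level <= 0 or np.allclose(shifted, 0):
        crossings = np.array([])
    else:
        roots = np.polynomial.polynomial.polyroots(shifted)
        real = roots[np.abs(roots.imag) < 1e-8].real
        crossings = np.sort(real[(real >= 0.0) & (real <= 1.0)])
    return BoundaryFit(
        coefficients=coeffs, sigma_level=float(sigma_level), crossings=crossings
    )
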