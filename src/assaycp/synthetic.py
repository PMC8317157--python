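"""Synthetic two-assay dataset generator.

Emulates the situation of a QSAR endpoint measured by a legacy ("old") and
a replacement ("new") assay, so that every modeling strategy can be
exercised without proprietary screening data. The generative model:

* Compounds are sparse non-negative signature-like count vectors. Each
  assay samples compounds from its own region of descriptor space — the
  old assay from a broader support, the new assay from a narrower,
  partially overlapping one (the old assay has covered more chemistry).
* A latent potency (pIC50 scale) is linear in the descriptors plus
  compound-level noise: potency = 5 + s·z(x) + e, where z is the
  standardized descriptor score and e ~ N(0, σ_e).
* The new assay reports potency + ν; the old assay reports a systematic
  transformation 5 + a·(potency − 5) − b + ν with slope ``a`` and offset
  ``b`` (in pIC50; b > 0 means the old assay reports higher IC50s).
* Class balance is controlled by stratified sampling on the latent
  potency at the 10 μM threshold (pIC50 = 5), emulating the different
  active rates of the two historical datasets.

With slope 1, offset 0, full supports and equal active fractions the two
assays are statistically identical — the no-shift limit in which every
composition strategy must be valid.

An augmentation operation additionally disturbs old-assay measurements on
the IC50 scale, IC50' = IC50 + c·IC50² + G(5, 0.5), to simulate a
transition with much lower assay agreement, and a qualifier injector
censors high-IC50 records at the assay ceiling (">" records).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import (
    ACTIVE,
    CLASSIFICATION,
    NONACTIVE,
    REGRESSION,
    Assay,
    CompoundRecord,
    LabeledDataset,
    Qualifier,
    ic50_to_pic50,
    pic50_to_ic50,
)

#: pIC50 at the 10 μM activity threshold
THRESHOLD_PIC50 = 5.0


@dataclass
class GeneratorConfig:
    """Parameters of the two-assay generator.

    ``seed`` is mandatory; all sizes are counts of records, ``d`` is the
    descriptor dimension, ``nnz_mean`` the expected nonzeros per record.
    ``sigma_latent`` (σ_e) is compound-level potency noise not encoded in
    the descriptors and ``sigma_assay`` (ν) per-measurement noise, both in
    pIC50 units. Shift parameters: ``slope``/``offset_pic50`` transform the
    old assay's response, the support fractions control how much of
    descriptor space each assay draws from (old broader than new), and the
    active fractions set the class mix per assay at the 10 μM threshold.
    """

    seed: int
    n_old: int = 5000
    n_new: int = 500
    d: int = 500
    nnz_mean: float = 30.0
    count_mean: float = 1.0
    weight_scale: float = 1.0
    latent_scale: float = 1.0
    sigma_latent: float = 0.3
    sigma_assay: float = 0.2
    slope: float = 0.9
    offset_pic50: float = 0.1
    old_support_frac: float = 0.8
    new_support_frac: float = 0.4
    active_fraction_new: float = 0.45
    active_fraction_old: float = 0.30
    qualifier_rate: float = 0.0
    censor_ceiling_um: float = 100.0

    def __post_init__(self) -> None:
        if self.n_old <= 0 or self.n_new <= 0 or self.d <= 0:
            raise ValueError("counts and dimension must be positive")
        if self.sigma_latent < 0 or self.sigma_assay < 0:
            raise ValueError("noise scales must be non-negative")
        for f in (self.active_fraction_new, self.active_fraction_old):
            if not 0.0 < f < 1.0:
                raise ValueError("active fractions must lie in (0, 1)")
        if not 0.0 <= self.qualifier_rate < 1.0:
            raise ValueError("qualifier rate must lie in [0, 1)")
        for f in (self.old_support_frac, self.new_support_frac):
            if not 0.0 < f <= 1.0:
                raise ValueError("support fractions must lie in (0, 1]")

    @classmethod
    def no_shift(cls, seed: int, active_fraction: float = 0.45, **overrides):
        """The exchangeable limit: old and new assays are identical."""
        return cls(
            seed=seed,
            slope=1.0,
            offset_pic50=0.0,
            old_support_frac=1.0,
            new_support_frac=1.0,
            active_fraction_new=active_fraction,
            active_fraction_old=active_fraction,
            **overrides,
        )

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class AugmentConfig:
    """IC50-scale disturbance of old-assay measurements.

    IC50' = IC50 + quad_coeff·IC50² + G(noise_mean, noise_sd), everything
    in μM; non-positive results are clipped to ``floor_um``.
    """

    quad_coeff: float = 0.01
    noise_mean: float = 5.0
    noise_sd: float = 0.5
    floor_um: float = 0.001

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if self.floor_um <= 0:
            raise ValueError("clipping floor must be positive")


# ---------------------------------------------------------------------------
# feature and potency machinery
# ---------------------------------------------------------------------------


def _supports(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    old_width = max(1, int(round(cfg.d * cfg.old_support_frac)))
    new_width = max(1, int(round(cfg.d * cfg.new_support_frac)))
    old_support = np.arange(0, old_width)
    new_support = np.arange(cfg.d - new_width, cfg.d)
    return old_support, new_support


def _sample_features(
    rng: np.random.Generator, n: int, support: np.ndarray, cfg: GeneratorConfig
) -> sp.csr_matrix:
    max_nnz = len(support)
    nnz = np.clip(rng.poisson(cfg.nnz_mean, size=n), 1, max_nnz)
    rows, cols, data = [], [], []
    for i in range(n):
        m = int(nnz[i])
        idx = rng.choice(support, size=m, replace=False)
        counts = 1 + rng.poisson(cfg.count_mean, size=m)
        rows.extend([i] * m)
        cols.extend(idx.tolist())
        data.extend(counts.tolist())
    return sp.csr_matrix((data, (rows, cols)), shape=(n, cfg.d), dtype=float)


def _stratified_pick(
    rng: np.random.Generator, active_mask: np.ndarray, n: int, frac: float
):
    """Indices of n pool rows with ≈ frac actives (latent threshold)."""
    act = np.flatnonzero(active_mask)
    inact = np.flatnonzero(~active_mask)
    n_act = int(round(frac * n))
    n_inact = n - n_act
    if n_act > act.size or n_inact > inact.size:
        n_act = min(n_act, act.size)
        n_inact = min(n - n_act, inact.size)
        n_act = min(n - n_inact, act.size)
        warnings.warn(
            "infeasible active-fraction target; achieved fraction "
            f"{n_act / max(n_act + n_inact, 1):.3f}",
            stacklevel=3,
        )
    picked = np.concatenate(
        [
            rng.choice(act, size=n_act, replace=False),
            rng.choice(inact, size=n_inact, replace=False),
        ]
    )
    rng.shuffle(picked)
    return picked


def _assay_sample(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    w: np.ndarray,
    support: np.ndarray,
    n: int,
    frac: float,
):
    """Draw n compounds from one assay's chemical space with ≈ frac actives.

    Returns ``(X, potency)`` where potency is the latent true pIC50.
    """
    n_pool = int(np.ceil(2.3 * n * max(frac, 1.0 - frac) / 0.5)) + 64
    X = _sample_features(rng, n_pool, support, cfg)
    raw = X @ w
    sd = float(np.std(raw))
    z = (raw - float(np.mean(raw))) / (sd if sd > 0 else 1.0)
    potency = (
        THRESHOLD_PIC50
        + cfg.latent_scale * z
        + rng.normal(0.0, cfg.sigma_latent, size=n_pool)
    )
    picked = _stratified_pick(rng, potency >= THRESHOLD_PIC50, n, frac)
    return sp.csr_matrix(X[picked]), potency[picked]


def _reported(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    potency: np.ndarray,
    assay: Assay,
) -> np.ndarray:
    noise = rng.normal(0.0, cfg.sigma_assay, size=len(potency))
    if assay is Assay.NEW:
        return potency + noise
    return (
        THRESHOLD_PIC50
        + cfg.slope * (potency - THRESHOLD_PIC50)
        - cfg.offset_pic50
        + noise
    )


# ---------------------------------------------------------------------------
# public generation operations
# ---------------------------------------------------------------------------


def generate_two_assay(cfg: GeneratorConfig, task: str = REGRESSION):
    """Generate ``(A_old, A_new, truth)`` labeled datasets.

    Regression targets are the reported pIC50 values; classification
    labels are active/nonactive at the 10 μM threshold applied to the
    reported value. ``truth`` carries the descriptor weights, latent
    potencies and reported values for both assays.
    """
    if task not in (CLASSIFICATION, REGRESSION):
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    w = rng.normal(0.0, cfg.weight_scale, size=cfg.d)
    old_support, new_support = _supports(cfg)

    X_old, pot_old = _assay_sample(
        rng, cfg, w, old_support, cfg.n_old, cfg.active_fraction_old
    )
    X_new, pot_new = _assay_sample(
        rng, cfg, w, new_support, cfg.n_new, cfg.active_fraction_new
    )
    rep_old = _reported(rng, cfg, pot_old, Assay.OLD)
    rep_new = _reported(rng, cfg, pot_new, Assay.NEW)

    def build(X, rep, tag, n):
        if task == REGRESSION:
            y = rep.astype(float)
        else:
            y = np.where(rep >= THRESHOLD_PIC50, ACTIVE, NONACTIVE).astype(object)
        return LabeledDataset(
            X=X,
            y=y,
            assay_tag=np.full(n, tag, dtype=object),
            task=task,
            compound_ids=np.array([f"{tag}_{i:06d}" for i in range(n)], dtype=object),
        )

    truth = {
        "w": w,
        "old_support": old_support,
        "new_support": new_support,
        "potency_old": pot_old,
        "potency_new": pot_new,
        "reported_old": rep_old,
        "reported_new": rep_new,
        "config": cfg,
    }
    return (
        build(X_old, rep_old, "old", cfg.n_old),
        build(X_new, rep_new, "new", cfg.n_new),
        truth,
    )


def generate_compound_records(cfg: GeneratorConfig):
    """Generate raw per-measurement records for the CSV/prep pipeline.

    Returns ``(old_records, new_records, truth)``; IC50s are on the μM
    scale, test dates place the old assay before the new one, and a
    nonzero ``qualifier_rate`` censors high-IC50 records at the assay
    ceiling.
    """
    A_old, A_new, truth = generate_two_assay(cfg, task=REGRESSION)

    def to_records(ds: LabeledDataset, assay: Assay, start: dt.date):
        recs = []
        for i in range(ds.n):
            row = ds.X[i]
            feats = {int(j): int(v) for j, v in zip(row.indices, row.data)}
            recs.append(
                CompoundRecord(
                    compound_id=str(ds.compound_ids[i]),
                    ic50_um=float(pic50_to_ic50(float(ds.y[i]))),
                    qualifier=Qualifier.EXACT,
                    test_date=start + dt.timedelta(days=i % 1400),
                    assay=assay,
                    features=feats,
                )
            )
        return recs

    old_records = to_records(A_old, Assay.OLD, dt.date(2012, 1, 1))
    new_records = to_records(A_new, Assay.NEW, dt.date(2018, 1, 1))
    if cfg.qualifier_rate > 0:
        old_records = inject_qualifiers(
            old_records, cfg.qualifier_rate, int(cfg.seed) + 1, cfg.censor_ceiling_um
        )
        new_records = inject_qualifiers(
            new_records, cfg.qualifier_rate, int(cfg.seed) + 2, cfg.censor_ceiling_um
        )
    return old_records, new_records, truth


def generate_paired_measurements(cfg: GeneratorConfig, n_pairs: int):
    """Simulate compounds measured in both assays (concordance pairs).

    Compounds are drawn from the new assay's chemical space (re-tested
    compounds); returns ``(old_ic50_um, new_ic50_um)`` arrays.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))
    w = rng.normal(0.0, cfg.weight_scale, size=cfg.d)
    _, new_support = _supports(cfg)
    _, potency = _assay_sample(
        rng, cfg, w, new_support, n_pairs, cfg.active_fraction_new
    )
    old = _reported(rng, cfg, potency, Assay.OLD)
    new = _reported(rng, cfg, potency, Assay.NEW)
    return pic50_to_ic50(old), pic50_to_ic50(new)


def augment_old_assay(
    A_old: LabeledDataset, cfg: AugmentConfig | None = None, seed: int = 0
) -> LabeledDataset:
    """Disturb old-assay measurements on the IC50 scale.

    IC50' = IC50 + c·IC50² + G(μ_G, σ_G); descriptors are unchanged.
    Non-positive disturbed values are clipped to the configured floor and
    the clip count is reported via a warning.
    """
    cfg = cfg or AugmentConfig()
    if A_old.task != REGRESSION:
        raise ValueError("augmentation operates on regression (pIC50) datasets")
    rng = np.random.default_rng(seed)
    ic50 = pic50_to_ic50(A_old.y.astype(float))
    noise = rng.normal(cfg.noise_mean, cfg.noise_sd, size=len(ic50))
    disturbed = ic50 + cfg.quad_coeff * ic50**2 + noise
    n_clipped = int(np.sum(disturbed <= cfg.floor_um))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} augmented IC50(s) clipped to {cfg.floor_um} μM",
            stacklevel=2,
        )
    disturbed = np.maximum(disturbed, cfg.floor_um)
    return LabeledDataset(
        X=A_old.X,
        y=ic50_to_pic50(disturbed),
        assay_tag=A_old.assay_tag,
        task=REGRESSION,
        compound_ids=A_old.compound_ids,
    )


def inject_qualifiers(
    records, rate: float, seed: int = 0, ceiling_um: float = 100.0
):
    """Censor a Binomial(n, rate) draw of the highest-IC50 records.

    Censored records get qualifier ">" with the IC50 set to the assay
    ceiling, mimicking measurements outside the tested concentration
    range. Rate 0 returns the records unchanged.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    records = list(records)
    if rate == 0.0 or not records:
        return records
    rng = np.random.default_rng(seed)
    n = len(records)
    n_censor = int(rng.binomial(n, rate))
    if n_censor == 0:
        return records
    order = np.argsort([-r.ic50_um for r in records], kind="stable")[:n_censor]
    to_censor = set(int(i) for i in order)
    out = []
    for i, r in enumerate(records):
        if i in to_censor:
            out.append(
                dataclasses.replace(
                    r, qualifier=Qualifier.GREATER, ic50_um=ceiling_um
                )
            )
        else:
            out.append(r)
    return out
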