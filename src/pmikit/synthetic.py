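"""Synthetic post-mortem metabolomic cohorts with known ground truth.

Emulates the statistical structure of a forensic toxicology cohort:

* a skewed discrete PMI distribution (median 5 days, range 1-67, ~97%
  of cases within 1-13 days), modeled as a rounded log-normal;
* a few hundred LC-MS features on a log-intensity scale, subsets of
  which decrease, increase, or fluctuate with PMI, the rest pure noise;
* zero inflation: a fixed fraction of raw intensities set to exactly 0,
  preferentially where the true abundance is low (below-LOD semantics);
* a second "platform" whose feature catalog is the first's with bounded
  m/z (ppm) and retention-time (seconds) jitter plus exclusive novel
  features, with the planted correspondence recorded for harmonization
  tests.

Nothing here simulates raw spectra, peak shapes, or within-platform
batch drift.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import DeathRecord
from .tables import FeatureTable

FEATURE_CLASSES = ("decreasing", "increasing", "fluctuating", "noise")


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PMIShape:
    """Parameters of the discrete PMI sampler.

    A log-normal with median ``median_days`` is rounded to integer days
    and clipped to ``[1, max_days]``. ``sigma`` is derived so that
    ``P(PMI <= upper_days) = upper_prob`` (with half-integer continuity
    correction), pinning the sampler to the three cohort facts it
    encodes: median 5, 97% within 1-13, range 1-67.
    """

    median_days: float = 5.0
    upper_days: int = 13
    upper_prob: float = 0.97
    max_days: int = 67

    @property
    def mu(self) -> float:
        return float(np.log(self.median_days))

    @property
    def sigma(self) -> float:
        z = stats.norm.ppf(self.upper_prob)
        return float((np.log(self.upper_days + 0.5) - self.mu) / z)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults give the desk-scale cohort used throughout the test suite:
    1500 samples, 300 features of which 15% decrease, 15% increase and
    10% fluctuate with PMI (the remaining 60% are uninformative noise),
    slope magnitude 1.0 on the ln-intensity scale, residual noise SD 0.5
    and 15% zero inflation.
    """

    n_samples: int = 1500
    n_features: int = 300
    frac_decreasing: float = 0.15
    frac_increasing: float = 0.15
    frac_fluctuating: float = 0.10
    effect_size: float = 1.0
    noise_sd: float = 0.5
    zero_inflation_rate: float = 0.15
    pmi_shape: PMIShape = field(default_factory=PMIShape)
    male_fraction: float = 0.723
    platform: str = "platformA"
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_decreasing, self.frac_increasing, self.frac_fluctuating)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1 + 1e-12:
            raise SynthConfigError(
                f"class fractions must lie in [0,1] and sum to <= 1, got {fr}"
            )
        if self.n_samples < 2:
            raise SynthConfigError("n_samples must be >= 2")
        if self.n_features < 1:
            raise SynthConfigError("n_features must be >= 1")
        if self.noise_sd < 0:
            raise SynthConfigError("noise_sd must be >= 0")
        if not 0 <= self.zero_inflation_rate <= 1:
            raise SynthConfigError("zero_inflation_rate must be in [0,1]")


@dataclass
class GroundTruth:
    """Planted per-feature class labels and noise-free trajectories."""

    feature_class: pd.Series  # index feature_id, values in FEATURE_CLASSES
    true_trajectory: pd.DataFrame  # features x PMI grid (integer days)

    @property
    def pmi_grid(self) -> np.ndarray:
        return self.true_trajectory.columns.to_numpy()

    def informative_ids(self) -> list[str]:
        return list(self.feature_class.index[self.feature_class != "noise"])

    def write(self, path) -> None:
        self.feature_class.rename("class").rename_axis("feature_id").to_csv(path)


@dataclass
class TrueMatching:
    """Planted cross-platform correspondence (oracle for harmonization).

    ``pairs`` maps every reference feature id to its partner id on the
    second platform, or None where the partner was dropped.
    """

    pairs: dict[str, str | None]

    def __post_init__(self) -> None:
        partners = [v for v in self.pairs.values() if v is not None]
        if len(partners) != len(set(partners)):
            raise SynthConfigError("a new feature is matched more than once")

    def n_matched(self) -> int:
        return sum(v is not None for v in self.pairs.values())


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def sample_pmi(rng: np.random.Generator, n: int, shape: PMIShape) -> np.ndarray:
    """Integer PMI days from the rounded, clipped log-normal."""
    x = rng.lognormal(mean=shape.mu, sigma=shape.sigma, size=n)
    return np.clip(np.rint(x).astype(int), 1, shape.max_days)


def _pmi_curve(grid: np.ndarray, shape: PMIShape) -> np.ndarray:
    """Monotone time axis g(t) = ln t / ln max_days in [0, 1]."""
    return np.log(grid) / np.log(shape.max_days)


def _trajectories(
    rng: np.random.Generator, classes: np.ndarray, cfg: SynthConfig
) -> np.ndarray:
    """Noise-free log-intensity offsets, one row per feature over 1..max."""
    grid = np.arange(1, cfg.pmi_shape.max_days + 1)
    g = _pmi_curve(grid, cfg.pmi_shape)
    # fluctuating features share cohort-level phases (a co-regulated
    # degradation process) with per-feature amplitude mixes; their wave
    # completes a full period over the densely observed PMI range, so
    # the class is genuinely non-monotone where the cohort has data
    gw = np.log(grid) / np.log(cfg.pmi_shape.upper_days)
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    out = np.zeros((len(classes), len(grid)))
    for i, cls in enumerate(classes):
        if cls == "decreasing":
            out[i] = -cfg.effect_size * g
        elif cls == "increasing":
            out[i] = cfg.effect_size * g
        elif cls == "fluctuating":
            c1, c2 = rng.uniform(0.5, 1.0, size=2)
            wave = c1 * np.cos(2 * np.pi * gw + phi1) + c2 * np.cos(
                4 * np.pi * gw + phi2
            )
            out[i] = cfg.effect_size * wave / (c1 + c2)
    return out


def _assign_classes(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    n = cfg.n_features
    counts = [
        int(round(cfg.frac_decreasing * n)),
        int(round(cfg.frac_increasing * n)),
        int(round(cfg.frac_fluctuating * n)),
    ]
    if sum(counts) > n:
        raise SynthConfigError("class fractions leave no room for features")
    labels = np.array(
        ["decreasing"] * counts[0]
        + ["increasing"] * counts[1]
        + ["fluctuating"] * counts[2]
        + ["noise"] * (n - sum(counts)),
        dtype=object,
    )
    rng.shuffle(labels)
    return labels


def _feature_coordinates(
    rng: np.random.Generator,
    n: int,
    existing_mz: np.ndarray | None = None,
    existing_rt: np.ndarray | None = None,
    min_sep_ppm: float = 25.0,
    min_sep_rt: float = 120.0,
    mz_range: tuple[float, float] = (80.0, 1000.0),
    rt_range: tuple[float, float] = (20.0, 1200.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Draw m/z / RT coordinates so distinct features stay resolvable.

    Two features may sit close in m/z only if they are far apart in RT
    (and vice versa), guaranteeing unambiguous matching under jitters
    smaller than half the default tolerance windows.
    """
    mzs = list(existing_mz) if existing_mz is not None else []
    rts = list(existing_rt) if existing_rt is not None else []
    n_existing = len(mzs)
    for _ in range(n):
        for _attempt in range(1000):
            mz = rng.uniform(*mz_range)
            rt = rng.uniform(*rt_range)
            if mzs:
                dmz_ppm = np.abs(np.asarray(mzs) - mz) / mz * 1e6
                drt = np.abs(np.asarray(rts) - rt)
                if ((dmz_ppm < min_sep_ppm) & (drt < min_sep_rt)).any():
                    continue
            mzs.append(mz)
            rts.append(rt)
            break
        else:  # pragma: no cover - only reachable at absurd densities
            raise SynthConfigError("could not place separated feature coordinates")
    return np.asarray(mzs[n_existing:]), np.asarray(rts[n_existing:])


DETECTION_SHARPNESS = 4.0  # steepness of the soft LOD threshold, 1/ln-units


def _zero_inflate(
    rng: np.random.Generator, raw: np.ndarray, log_abundance: np.ndarray, rate: float
) -> np.ndarray:
    """Censor exactly round(rate * size) entries below a soft LOD.

    Zeros model peaks falling under the instrument's limit of detection,
    so they are taken from the *lowest* realized log abundances: the
    Gumbel top-k trick with weights exp(-sharpness * log_abundance) is a
    softened bottom-k by abundance, i.e. a detection threshold with a
    narrow stochastic margin rather than a hard cut.
    """
    if rate == 0:
        return raw
    k = int(round(rate * raw.size))
    if k == 0:
        return raw
    gumbel = rng.gumbel(size=raw.size)
    score = -DETECTION_SHARPNESS * log_abundance.ravel() + gumbel
    idx = np.argpartition(score, -k)[-k:]
    out = raw.copy()
    out.ravel()[idx] = 0.0
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _build_samples(
    rng: np.random.Generator, cfg: SynthConfig, prefix: str
) -> pd.DataFrame:
    pmi = sample_pmi(rng, cfg.n_samples, cfg.pmi_shape)
    sex = np.where(
        rng.uniform(size=cfg.n_samples) < cfg.male_fraction, "male", "female"
    )
    ids = [f"{prefix}{i:05d}" for i in range(cfg.n_samples)]
    return pd.DataFrame(
        {"pmi_days": pmi, "sex": sex, "platform": cfg.platform},
        index=pd.Index(ids, name="sample_id"),
    )


def _build_intensities(
    rng: np.random.Generator,
    cfg: SynthConfig,
    pmi: np.ndarray,
    base: np.ndarray,
    traj: np.ndarray,
) -> np.ndarray:
    # log-intensity = per-feature baseline + class trajectory + noise
    log_signal = base[None, :] + traj[:, pmi - 1].T
    noise = rng.normal(scale=cfg.noise_sd, size=log_signal.shape) if cfg.noise_sd else 0.0
    log_abund = np.maximum(log_signal + noise, 0.0)
    raw = np.expm1(log_abund)
    return _zero_inflate(rng, raw, log_abund, cfg.zero_inflation_rate)


def generate_cohort(config: SynthConfig) -> tuple[FeatureTable, GroundTruth]:
    """One synthetic cohort plus its planted ground truth.

    Raw intensities are non-negative with exact ``ln(x+1)`` inverse
    structure: noise-free features are strictly monotone in PMI when
    their class says so. Identical configs (including seed) reproduce
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    classes = _assign_classes(rng, config)
    traj = _trajectories(rng, classes, config)
    base = rng.uniform(4.0, 8.0, size=config.n_features)
    mz, rt = _feature_coordinates(rng, config.n_features)
    sample_meta = _build_samples(rng, config, prefix="S")
    raw = _build_intensities(rng, config, sample_meta["pmi_days"].to_numpy(), base, traj)

    feature_ids = pd.Index(
        [f"F{i:05d}" for i in range(config.n_features)], name="feature_id"
    )
    feature_meta = pd.DataFrame({"mz_median": mz, "rt_median": rt}, index=feature_ids)
    intensities = pd.DataFrame(raw, index=sample_meta.index, columns=feature_ids)
    table = FeatureTable(intensities, sample_meta, feature_meta)

    grid = np.arange(1, config.pmi_shape.max_days + 1)
    truth = GroundTruth(
        feature_class=pd.Series(classes, index=feature_ids, name="class"),
        true_trajectory=pd.DataFrame(traj, index=feature_ids, columns=grid),
    )
    return table, truth


def generate_platform_pair(
    config: SynthConfig,
    mz_jitter_ppm: float = 2.0,
    rt_jitter: float = 10.0,
    frac_exclusive: float = 0.3,
) -> tuple[FeatureTable, FeatureTable, TrueMatching]:
    """A reference cohort plus a second-platform cohort for harmonization.

    The second platform shares ``1 - frac_exclusive`` of the reference
    features (coordinates perturbed by bounded uniform jitter: ppm in
    m/z, seconds in RT), drops the rest, and gains the same number of
    novel exclusive features. The planted correspondence is returned.
    """
    if mz_jitter_ppm < 0 or rt_jitter < 0:
        raise SynthConfigError("jitters must be >= 0")
    if not 0 <= frac_exclusive < 1:
        raise SynthConfigError("frac_exclusive must be in [0, 1)")

    ref_table, truth = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))

    n_feat = config.n_features
    n_shared = n_feat - int(round(frac_exclusive * n_feat))
    shared_idx = np.sort(rng.choice(n_feat, size=n_shared, replace=False))

    ref_mz = ref_table.feature_meta["mz_median"].to_numpy()
    ref_rt = ref_table.feature_meta["rt_median"].to_numpy()
    jit_mz = ref_mz[shared_idx] * (
        1 + mz_jitter_ppm * 1e-6 * rng.uniform(-1, 1, size=n_shared)
    )
    jit_rt = np.maximum(
        ref_rt[shared_idx] + rt_jitter * rng.uniform(-1, 1, size=n_shared), 0.0
    )
    n_excl = n_feat - n_shared
    excl_mz, excl_rt = _feature_coordinates(
        rng, n_excl, existing_mz=ref_mz, existing_rt=ref_rt
    )

    new_mz = np.concatenate([jit_mz, excl_mz])
    new_rt = np.concatenate([jit_rt, excl_rt])
    order = rng.permutation(len(new_mz))
    new_ids = pd.Index(
        [f"N{i:05d}" for i in range(len(new_mz))], name="feature_id"
    )
    new_meta = pd.DataFrame(
        {"mz_median": new_mz[order], "rt_median": new_rt[order]}, index=new_ids
    )

    # second cohort: new individuals, same biology for shared features
    cfg2 = replace(config, platform=config.platform + "_B")
    traj_all = np.concatenate(
        [truth.true_trajectory.to_numpy()[shared_idx], np.zeros((n_excl, truth.true_trajectory.shape[1]))]
    )[order]
    base = rng.uniform(4.0, 8.0, size=n_feat)
    sample_meta = _build_samples(rng, cfg2, prefix="T")
    raw = _build_intensities(
        rng, cfg2, sample_meta["pmi_days"].to_numpy(), base, traj_all
    )
    new_table = FeatureTable(
        pd.DataFrame(raw, index=sample_meta.index, columns=new_ids),
        sample_meta,
        new_meta,
    )

    inverse = np.empty(len(order), dtype=int)
    inverse[order] = np.arange(len(order))
    pairs: dict[str, str | None] = {}
    ref_ids = list(ref_table.feature_meta.index)
    for pos, ref_i in enumerate(shared_idx):
        pairs[ref_ids[ref_i]] = str(new_ids[inverse[pos]])
    for ref_i in range(n_feat):
        pairs.setdefault(ref_ids[ref_i], None)
    pairs = {rid: pairs[rid] for rid in ref_ids}
    return ref_table, new_table, TrueMatching(pairs)


# ---------------------------------------------------------------------------
# Death-record fixtures
# ---------------------------------------------------------------------------

STUDY_START = _dt.date(2017, 9, 1)
STUDY_END = _dt.date(2019, 3, 14)
PROBABLE_RATE = 922 / 4876  # registry composition of the emulated cohort


def simulate_death_records(
    n: int,
    seed: int = 0,
    probable_rate: float = PROBABLE_RATE,
    shape: PMIShape | None = None,
) -> list[DeathRecord]:
    """Seeded death/autopsy record fixtures.

    Death dates fall in a ~1.5-year intake window; the autopsy follows
    after a PMI drawn from the cohort sampler; a fraction of records is
    coded ``probable`` (death date inferred from when the deceased was
    last seen alive).
    """
    if n < 1:
        raise SynthConfigError("n must be >= 1")
    shape = shape or PMIShape()
    rng = np.random.default_rng(seed)
    window = (STUDY_END - STUDY_START).days
    offsets = rng.integers(0, window + 1, size=n)
    pmis = sample_pmi(rng, n, shape)
    probable = rng.uniform(size=n) < probable_rate
    records = []
    for off, pmi, prob in zip(offsets, pmis, probable):
        death = STUDY_START + _dt.timedelta(days=int(off))
        records.append(
            DeathRecord(
                death_date=death,
                autopsy_date=death + _dt.timedelta(days=int(pmi)),
                certainty="probable" if prob else "certain",
                last_seen_date=death if prob else None,
            )
        )
    return records
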