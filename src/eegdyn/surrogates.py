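"""Stationary surrogate time series and surrogate-based statistics.

Nonstationarity of the dynamics-matrix measures is tested against surrogate
multichannel series that preserve (a) each channel's exact amplitude
distribution, (b) each channel's power spectrum, and (c) the zero-lag
cross-correlation between channels, while destroying any nonstationary
temporal structure.  The construction is a multivariate iterative
amplitude-adjusted Fourier transform (IAAFT): all channels receive a common
random phase increment (which preserves the cross-spectrum), and the
iteration alternates a spectral adjustment step with per-channel rank-ordered
amplitude restoration.

Measures computed on an ensemble of such surrogates form the null
distribution for z-scoring the empirical measures: values well outside
roughly [-2, 2] cannot be explained by stationary fluctuations around the
segment's average spectral and correlation composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Segment
from .measures import FEATURE_NAMES, FeatureVector, compute_segment_features

__all__ = [
    "SurrogateEnsemble",
    "ZScoredFeatures",
    "TestResult",
    "make_surrogates",
    "null_distribution",
    "zscore_features",
    "stationarity_ttest",
    "mixed_anova",
]

#: IAAFT convergence tolerance on the relative spectral error.
IAAFT_TOL = 1e-4
#: IAAFT iteration cap.
IAAFT_MAX_ITER = 100
#: Iterations during which the common-rotation (cross-spectrum preserving)
#: phase step is enforced before per-channel refinement takes over.
IAAFT_COMMON_PHASE_ITER = 10


@dataclass
class SurrogateEnsemble:
    """Null distribution of the 36 measures for one segment."""

    segment_id: str
    count: int
    surrogate_features: np.ndarray      # count x 36, canonical column order
    seed: int

    @property
    def means(self) -> np.ndarray:
        return self.surrogate_features.mean(axis=0)

    @property
    def sds(self) -> np.ndarray:
        return self.surrogate_features.std(axis=0, ddof=1)


@dataclass
class ZScoredFeatures:
    """Surrogate-normalized measures; NaN where the null SD is zero."""

    segment_id: str
    z: dict[str, float]
    undefined: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    dof: tuple
    p_value: float
    test_name: str


# ---------------------------------------------------------------------------
# Multivariate IAAFT
# ---------------------------------------------------------------------------

def _iaaft_one(data: np.ndarray, rng: np.random.Generator,
               tol: float, max_iter: int) -> np.ndarray:
    """One multivariate IAAFT surrogate of a channels x samples array."""
    n, T = data.shape
    target_amp = np.abs(np.fft.rfft(data, axis=1))
    theta = np.angle(np.fft.rfft(data, axis=1))
    sorted_vals = np.sort(data, axis=1)
    amp_norm = np.linalg.norm(target_amp, axis=1)
    amp_norm[amp_norm == 0] = 1.0

    # Common random phase increment per frequency preserves all phase
    # differences between channels, hence the cross-spectrum.
    nf = target_amp.shape[1]
    phi = rng.uniform(0.0, 2.0 * np.pi, size=nf)
    phi[0] = 0.0
    if T % 2 == 0:
        phi[-1] = 0.0  # Nyquist bin must stay real
    s = np.fft.irfft(target_amp * np.exp(1j * (theta + phi)), n=T, axis=1)

    def rank_remap(x):
        # place the original sorted values at the ranks of x
        order = np.argsort(x, axis=1)
        out = np.empty_like(x)
        np.put_along_axis(out, order, sorted_vals, axis=1)
        return out

    for it in range(max_iter):
        # amplitude restoration: rank-order remap to the original values
        s = rank_remap(s)
        # convergence: relative spectral error after amplitude restoration
        spec = np.fft.rfft(s, axis=1)
        err = np.linalg.norm(np.abs(spec) - target_amp, axis=1) / amp_norm
        if float(err.max()) < tol:
            return s
        psi = np.angle(spec)
        if it < IAAFT_COMMON_PHASE_ITER:
            # rotate the original phase pattern by a common per-frequency
            # angle closest to the current phases (amplitude-weighted
            # circular mean); keeps the cross-spectrum exact
            rot = np.angle(np.sum(target_amp * np.exp(1j * (psi - theta)),
                                  axis=0))
            rot[0] = 0.0
            if T % 2 == 0:
                rot[-1] = 0.0
            psi = theta + rot
        # spectral step: restore target amplitudes at the chosen phases;
        # after the common-phase iterations the per-channel phases refine
        # freely, starting from a cross-spectrum-preserving solution
        s = np.fft.irfft(target_amp * np.exp(1j * psi), n=T, axis=1)
    # final amplitude restoration if the loop hit the iteration cap
    return rank_remap(s)


def make_surrogates(segment: Segment, count: int = 100, seed: int = 0,
                    tol: float = IAAFT_TOL,
                    max_iter: int = IAAFT_MAX_ITER) -> list[Segment]:
    """Generate ``count`` stationary surrogates of a raw (pre-filter) segment.

    Each surrogate preserves, per channel, the exact multiset of sample
    values; spectra and zero-lag cross-correlations are preserved to the
    convergence tolerance.  Deterministic given ``seed``.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if segment.duration < 2.0:
        raise ValueError("segment shorter than 2 s; surrogate spectra would "
                         "be too coarse")
    rng = np.random.default_rng([int(seed), 911])
    out = []
    for i in range(count):
        s = _iaaft_one(segment.data, rng, tol, max_iter)
        out.append(Segment(f"{segment.parent_id}#surr{i:03d}", s, segment.fs,
                           band=None, offset_s=segment.offset_s))
    return out


def null_distribution(surrogates: list[Segment], step: int = 1,
                      window_len: float = 2.0, segment_id: str = "",
                      seed: int = 0) -> SurrogateEnsemble:
    """Run the full windows + measures pipeline on every surrogate."""
    if len(surrogates) < 2:
        raise ValueError("need at least 2 surrogates for a null distribution")
    feats = np.empty((len(surrogates), len(FEATURE_NAMES)))
    for i, s in enumerate(surrogates):
        fv = compute_segment_features(s, step=step, window_len=window_len)
        feats[i] = fv.as_array()
    return SurrogateEnsemble(segment_id=segment_id, count=len(surrogates),
                             surrogate_features=feats, seed=seed)


def zscore_features(empirical: FeatureVector,
                    ensemble: SurrogateEnsemble) -> ZScoredFeatures:
    """z_i = (empirical_i - mean(null_i)) / sd(null_i); NaN where sd = 0."""
    emp = empirical.as_array()
    mu, sd = ensemble.means, ensemble.sds
    undefined = [name for name, s in zip(FEATURE_NAMES, sd) if s == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (emp - mu) / np.where(sd > 0, sd, 1.0), np.nan)
    return ZScoredFeatures(segment_id=empirical.segment_id,
                           z=dict(zip(FEATURE_NAMES, map(float, z))),
                           undefined=undefined)


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def stationarity_ttest(zscores) -> TestResult:
    """Two-sided one-sample t test of mean zero on a set of z-scores."""
    z = np.asarray(list(zscores), dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 z-scores")
    if np.ptp(z) == 0:
        if z[0] == 0:
            return TestResult(0.0, (z.size - 1,), 1.0, "one-sample t")
        # zero variance, nonzero mean: p -> 0 limit
        return TestResult(float(np.sign(z[0]) * np.inf), (z.size - 1,), 0.0,
                          "one-sample t")
    t, p = stats.ttest_1samp(z, popmean=0.0)
    return TestResult(float(t), (z.size - 1,), float(p), "one-sample t")


def mixed_anova(values, subject_ids, group_labels) -> TestResult:
    """Between-subjects F of a balanced split-plot (mixed) ANOVA.

    One value per repeated segment, several segments per subject, one group
    per subject.  Requires a balanced design (equal segment counts per
    subject) and at least two subjects in each of at least two groups.
    """
    import pandas as pd

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "subject": list(subject_ids),
                       "group": list(group_labels)})
    per_subj_group = df.groupby("subject")["group"].nunique()
    if (per_subj_group > 1).any():
        raise ValueError("each subject must belong to exactly one group")
    counts = df.groupby("subject").size()
    if counts.nunique() != 1:
        raise ValueError(f"unbalanced design: segment counts per subject = "
                         f"{sorted(counts.unique())}")
    if counts.iloc[0] < 2:
        raise ValueError("need >= 2 repeated segments per subject")
    groups = df.groupby("group")["subject"].nunique()
    if len(groups) < 2 or (groups < 2).any():
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    n_groups = len(groups)
    n_subjects = df["subject"].nunique()
    dof = (n_groups - 1, n_subjects - n_groups)
    if np.ptp(df["value"].to_numpy()) == 0:
        return TestResult(0.0, dof, 1.0, "mixed ANOVA between-subjects")
    df["segment"] = df.groupby("subject").cumcount()

    import pingouin as pg

    table = pg.mixed_anova(data=df, dv="value", within="segment",
                           subject="subject", between="group")
    row = table[table["Source"] == "group"].iloc[0]
    p_col = "p_unc" if "p_unc" in table.columns else "p-unc"
    return TestResult(float(row["F"]), dof, float(row[p_col]),
                      "mixed ANOVA between-subjects")
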