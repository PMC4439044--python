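"""Natal-origin assignment from otolith ⁸⁷Sr/⁸⁶Sr profiles.

Strontium isotope ratios are inherited from ambient water and recorded in
the otolith as it grows, so the early (post-yolk-sac) portion of a transect
carries the natal river's signature. A one-dimensional linear discriminant
classifier (per-site Gaussians with pooled variance and equal priors — in
1-D exactly LDA) trained on a known-origin isoscape assigns each adult to a
natal source; fish assigned away from the focal river are strays. Scanning
the profile outward, the natal-exit point is the last spot before the
posterior probability of focal-site membership both drops by more than 0.3
and falls below 0.5 (with a 2-SD fallback for gradual transitions); its
distance from the core is the radius used for size back-calculation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class IsotopeSpot:
    """One laser-ablation spot along a transect."""

    distance_from_core: float  # um
    ratio: float               # 87Sr/86Sr
    se: float = 0.0            # 2SE of the ratio
    index: int = 0


@dataclass
class OtolithProfile:
    """Ordered ⁸⁷Sr/⁸⁶Sr spots for one fish."""

    fish_id: str
    spots: list[IsotopeSpot]
    otolith_radius: float  # um

    def __post_init__(self):
        if len(self.spots) < 3:
            raise ValueError("profile needs at least 3 spots")
        d = self.distances
        if np.any(np.diff(d) <= 0):
            raise ValueError("spot distances must increase strictly")
        if d[-1] > self.otolith_radius + 1e-9:
            raise ValueError("last spot beyond otolith radius")

    @property
    def distances(self) -> np.ndarray:
        return np.array([s.distance_from_core for s in self.spots])

    @property
    def ratios(self) -> np.ndarray:
        return np.array([s.ratio for s in self.spots])

    @property
    def ses(self) -> np.ndarray:
        return np.array([s.se for s in self.spots])


@dataclass
class NatalAssignment:
    fish_id: str
    predicted_site: str
    posterior: dict[str, float]
    is_stray: bool
    natal_value: float = np.nan


@dataclass
class ExitPoint:
    """Natal-exit location along a profile (last natal spot)."""

    fish_id: str
    exit_index: int | None
    exit_radius: float
    defined: bool = True
    method: str = "posterior"


@dataclass
class IsoscapeClassifier:
    """1-D Gaussian discriminant with pooled variance and equal priors."""

    sites: list[str]
    means: np.ndarray
    pooled_sd: float
    site_sds: dict[str, float] = field(default_factory=dict)
    n_per_site: dict[str, int] = field(default_factory=dict)

    def log_likelihood(self, values) -> np.ndarray:
        x = np.atleast_1d(np.asarray(values, dtype=float))
        return -0.5 * ((x[:, None] - self.means[None, :]) / self.pooled_sd) ** 2

    def posterior(self, values) -> np.ndarray:
        """Posterior site probabilities (rows sum to 1; equal priors)."""
        ll = self.log_likelihood(values)
        return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))

    def classify(self, values, favour: str | None = None) -> np.ndarray:
        """Argmax site per value; near-ties (<1e-12) break toward ``favour``."""
        post = self.posterior(values)
        best = np.argmax(post, axis=1)
        if favour is not None and favour in self.sites:
            j = self.sites.index(favour)
            tie = post[np.arange(len(best)), best] - post[:, j] < 1e-12
            best[tie] = j
        return np.array([self.sites[i] for i in best])

    def restrict(self, sites: list[str]) -> "IsoscapeClassifier":
        keep = [self.sites.index(s) for s in sites]
        return IsoscapeClassifier(
            sites=list(sites), means=self.means[keep], pooled_sd=self.pooled_sd,
            site_sds={s: self.site_sds.get(s, self.pooled_sd) for s in sites},
            n_per_site={s: self.n_per_site.get(s, 0) for s in sites})


def train_isoscape(references: pd.DataFrame) -> IsoscapeClassifier:
    """Train the isoscape classifier from site-labelled reference ratios.

    ``references`` needs columns ``site`` and ``ratio`` (otolith and water
    reference samples are pooled with equal weight). Requires >=2 sites with
    >=2 samples each; the pooled within-site variance must be nonsingular.
    """
    g = references.groupby("site")["ratio"]
    counts, means, variances = g.count(), g.mean(), g.var(ddof=1)
    if len(counts) < 2:
        raise ValueError("need at least 2 sites")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"sites with <2 reference samples: {bad}")
    pooled_var = float(((counts - 1) * variances).sum() / (counts.sum() - len(counts)))
    if pooled_var <= 0:
        raise ValueError("singular pooled variance: references have no spread")
    order = means.sort_values().index.tolist()
    return IsoscapeClassifier(
        sites=order,
        means=means.loc[order].to_numpy(),
        pooled_sd=float(np.sqrt(pooled_var)),
        site_sds={s: float(np.sqrt(variances[s])) if counts[s] > 1 else float("nan")
                  for s in order},
        n_per_site={s: int(counts[s]) for s in order},
    )


def jackknife_scores(references: pd.DataFrame):
    """Leave-one-out reclassification of the reference samples.

    Returns ``(confusion, correct)``: an actual-by-predicted count matrix and
    the per-site correct-classification fraction. Sites with a single sample
    cannot be left out and are excluded with a warning.
    """
    counts = references.groupby("site")["ratio"].count()
    single = counts[counts < 2].index.tolist()
    if single:
        warnings.warn(f"excluding single-sample sites from jackknife: {single}",
                      stacklevel=2)
        references = references[~references["site"].isin(single)]
    sites = train_isoscape(references).sites
    confusion = pd.DataFrame(0, index=sites, columns=sites, dtype=int)
    refs = references.reset_index(drop=True)
    for i in range(len(refs)):
        loo = refs.drop(index=i)
        if (loo.groupby("site")["ratio"].count() < 2).any():
            # leaving this sample out would strand its site; refit without site
            loo = loo[loo["site"].isin(
                loo.groupby("site")["ratio"].count().pipe(lambda c: c[c >= 2]).index)]
        clf = train_isoscape(loo)
        pred = clf.classify([refs.loc[i, "ratio"]])[0]
        confusion.loc[refs.loc[i, "site"], pred] += 1
    correct = pd.Series(np.diag(confusion), index=sites) / confusion.sum(axis=1)
    return confusion, correct


def natal_value(profile: OtolithProfile, natal_window: int = 3,
                core_radius: float = 150.0) -> float:
    """Precision-weighted mean ratio of the natal-window spots.

    Uses the first ``natal_window`` spots beyond the core/yolk-sac region
    (``core_radius`` um), weighted by 1/SE² when spot SEs are available.
    """
    d, r, se = profile.distances, profile.ratios, profile.ses
    sel = np.flatnonzero(d > core_radius)[:natal_window]
    if len(sel) < natal_window:
        raise ValueError(
            f"profile {profile.fish_id}: fewer than {natal_window} spots "
            f"beyond core radius {core_radius} um")
    w = np.where(se[sel] > 0, 1.0 / np.maximum(se[sel], 1e-12) ** 2, np.nan)
    if np.any(~np.isfinite(w)):
        w = np.ones(len(sel))
    return float(np.sum(w * r[sel]) / np.sum(w))


def assign_natal(profile: OtolithProfile, classifier: IsoscapeClassifier,
                 focal_site: str, natal_window: int = 3,
                 core_radius: float = 150.0) -> NatalAssignment:
    """Assign a fish to its natal source and flag strays.

    The natal signature is the precision-weighted mean of the natal-window
    spots; the classifier posterior (equal priors) picks the source, ties
    breaking conservatively toward the focal site.
    """
    value = natal_value(profile, natal_window, core_radius)
    post = classifier.posterior([value])[0]
    pred = classifier.classify([value], favour=focal_site)[0]
    return NatalAssignment(
        fish_id=profile.fish_id,
        predicted_site=str(pred),
        posterior=dict(zip(classifier.sites, map(float, post))),
        is_stray=bool(pred != focal_site),
        natal_value=value,
    )


def detect_exit(profile: OtolithProfile, classifier: IsoscapeClassifier,
                focal_site: str, drop_threshold: float = 0.3,
                posterior_floor: float = 0.5,
                sd_multiplier: float = 2.0) -> ExitPoint:
    """Locate the natal-exit spot along a focal-site profile.

    The classifier is restricted to the focal site and its immediate
    downstream source (the site with the next-higher mean ratio), because
    natal exit is a two-source transition. Scanning spots in order, exit is
    the spot before the first one whose focal posterior both dropped by more
    than ``drop_threshold`` from the previous spot and is below
    ``posterior_floor``. If no spot triggers the rule (gradual ramps), the
    fallback is the last spot within ``sd_multiplier`` focal SDs of the
    focal mean before the first departure. A profile that never leaves the
    natal signature is returned flagged ``defined=False``.
    """
    if focal_site not in classifier.sites:
        raise ValueError(f"unknown focal site {focal_site!r}")
    i_focal = classifier.sites.index(focal_site)
    mu = classifier.means[i_focal]
    higher = [s for s in classifier.sites if classifier.means[classifier.sites.index(s)] > mu]
    if higher:
        downstream = min(higher, key=lambda s: classifier.means[classifier.sites.index(s)])
    else:  # focal has the highest mean; use nearest other site
        others = [s for s in classifier.sites if s != focal_site]
        downstream = min(others, key=lambda s: abs(
            classifier.means[classifier.sites.index(s)] - mu))
    two = classifier.restrict([focal_site, downstream])
    post = two.posterior(profile.ratios)[:, 0]

    for j in range(1, len(post)):
        if (post[j - 1] - post[j]) > drop_threshold and post[j] < posterior_floor:
            return ExitPoint(profile.fish_id, j - 1,
                             float(profile.distances[j - 1]), True, "posterior")

    sd = classifier.site_sds.get(focal_site)
    if sd is None or not np.isfinite(sd):
        sd = classifier.pooled_sd
    outside = np.flatnonzero(np.abs(profile.ratios - mu) > sd_multiplier * sd)
    if len(outside) == 0 or outside[0] == 0:
        return ExitPoint(profile.fish_id, None, float("nan"), False, "undefined")
    j = int(outside[0]) - 1
    return ExitPoint(profile.fish_id, j, float(profile.distances[j]), True, "2sd")
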