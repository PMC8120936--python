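"""Training and scoring of distance-dependent statistical potentials.

Two families of distance distributions are estimated from native chains:
a conditional model (one distribution per pair class) and a reference model
pooled over a prior representation.  Conformations are scored either as a
negative log-likelihood ratio between the two (PMF) or as a negated relative
difference (TIG); in both cases lower totals indicate more native-like
distance patterns.

Distributions are Gaussian kernel density estimates with the one-dimensional
Scott bandwidth, discretized on a fixed bin grid, floored and renormalized.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .representation import (
    PairKey,
    RepresentationSpec,
    Site,
    canonical_pair_key,
    project,
)
from .structure_io import Chain

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class DegenerateSamplesError(ValueError):
    """Raised when a bandwidth cannot be estimated (n < 2 or zero variance)."""


@dataclass
class TrainingConfig:
    """Cutoffs, grid and filters governing training and scoring."""

    train_cutoff: float = 17.0
    score_cutoff: float = 15.0
    bin_width: float = 0.5
    min_separation: int = 3
    probability_floor: float = 1e-10
    kde_bandwidth_rule: str = "scott"
    #: "per_class" fits a Scott bandwidth per distribution; "global" reuses
    #: the reference-sample bandwidth for every conditional class.
    bandwidth_scope: str = "per_class"
    #: renormalize trained distributions after truncation to score_cutoff
    renormalize_truncated: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.score_cutoff <= self.train_cutoff:
            raise ValueError("require 0 < score_cutoff <= train_cutoff")
        for cutoff in (self.train_cutoff, self.score_cutoff):
            n = cutoff / self.bin_width
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"bin width {self.bin_width} does not divide cutoff {cutoff}")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        if self.probability_floor <= 0:
            raise ValueError("probability_floor must be positive")
        if self.kde_bandwidth_rule != "scott":
            raise ValueError("only Scott's bandwidth rule is supported")
        if self.bandwidth_scope not in ("per_class", "global"):
            raise ValueError("bandwidth_scope must be 'per_class' or 'global'")

    def n_bins(self, cutoff: float) -> int:
        return round(cutoff / self.bin_width)


@dataclass(frozen=True)
class PairObservation:
    """One scored/counted site pair: its class and Euclidean distance (Å)."""

    key: PairKey
    distance: float


def collect_pairs(sites: Sequence[Site], cutoff: float,
                  min_separation: int) -> list[PairObservation]:
    """All unordered site pairs within ``cutoff`` whose parent residues are
    at least ``min_separation`` positions apart in the chain.

    Each unordered pair appears exactly once; intra-residue pairs never
    qualify (separation 0).
    """
    if len(sites) < 2:
        return []
    coords = np.array([s.coords for s in sites])
    ordinals = np.array([s.seq_ordinal for s in sites])
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return []
    i, j = pairs[:, 0], pairs[:, 1]
    keep = np.abs(ordinals[i] - ordinals[j]) >= min_separation
    i, j = i[keep], j[keep]
    dists = np.linalg.norm(coords[i] - coords[j], axis=1)
    return [PairObservation(canonical_pair_key(sites[a], sites[b]), float(d))
            for a, b, d in zip(i, j, dists)]


def scott_bandwidth(samples: Sequence[float]) -> float:
    """One-dimensional Scott rule: sample standard deviation times n^(-1/5)."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateSamplesError(f"need >= 2 samples, got {n}")
    sd = float(np.std(x, ddof=1))
    if sd < 1e-9:  # exact ties give sd ~ 1e-15 from rounding, not 0.0
        raise DegenerateSamplesError("zero variance samples")
    return sd * n ** (-1.0 / 5.0)


@dataclass
class DistanceDistribution:
    """A binned probability distribution over (0, cutoff]."""

    bin_edges: np.ndarray
    probs: np.ndarray
    n_samples: int
    bandwidth: float = 0.0
    low_confidence: bool = False
    #: False only for raw (non-renormalized) truncated scoring views
    normalized: bool = True

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != len(self.bin_edges) - 1:
            raise ValueError("probs/bin_edges length mismatch")
        if self.normalized and abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def cutoff(self) -> float:
        return float(self.bin_edges[-1])

    def bin_index(self, distance: float) -> int:
        """Half-open bins [k*w, (k+1)*w); the cutoff falls in the last bin."""
        return min(int(distance / self.bin_width), len(self.probs) - 1)

    def prob_at(self, distance: float) -> float:
        return float(self.probs[self.bin_index(distance)])

    def truncated(self, cutoff: float, floor: float,
                  renormalize: bool = True) -> "DistanceDistribution":
        """Restriction of the distribution to a shorter grid."""
        n = round(cutoff / self.bin_width)
        probs = self.probs[:n].copy()
        if renormalize:
            probs = _floor_and_normalize(probs, floor)
        return DistanceDistribution(self.bin_edges[:n + 1], probs,
                                    self.n_samples, self.bandwidth,
                                    self.low_confidence,
                                    normalized=renormalize)


def _floor_and_normalize(raw: np.ndarray, floor: float) -> np.ndarray:
    p = np.maximum(raw, floor)
    p = p / p.sum()
    p = np.maximum(p, floor)  # re-floor bins nudged below by normalization
    return p / p.sum()


def fit_distribution(samples: Sequence[float], cutoff: float,
                     config: TrainingConfig,
                     bandwidth: Optional[float] = None) -> DistanceDistribution:
    """Fit a binned KDE distribution to distance samples on (0, cutoff].

    Degenerate inputs fall back gracefully: identical samples produce a
    histogram (all mass in one bin), an empty sample set produces the
    floored uniform distribution flagged low-confidence.
    """
    x = np.asarray(samples, dtype=float)
    n_bins = config.n_bins(cutoff)
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    if x.size == 0:
        probs = _floor_and_normalize(np.ones(n_bins), config.probability_floor)
        return DistanceDistribution(edges, probs, 0, 0.0, low_confidence=True)
    if np.any((x <= 0) | (x > cutoff)):
        raise ValueError("samples must lie in (0, cutoff]")

    try:
        h = bandwidth if bandwidth is not None else scott_bandwidth(x)
        sd = float(np.std(x, ddof=1))
        if sd < 1e-9:
            raise DegenerateSamplesError("zero variance samples")
        kde = gaussian_kde(x, bw_method=h / sd)
        centers = (edges[:-1] + edges[1:]) / 2.0
        raw = kde(centers) * config.bin_width
    except DegenerateSamplesError:
        raw, _ = np.histogram(x, bins=edges)
        raw = raw.astype(float) / x.size
        h = 0.0
    probs = _floor_and_normalize(raw, config.probability_floor)
    return DistanceDistribution(edges, probs, int(x.size), float(h))


@dataclass
class ScoreResult:
    """Total score plus diagnostics for one scored chain."""

    total: float
    n_pairs: int
    per_pair_terms: Optional[list[float]] = None
    n_unknown_pairs: int = 0
    empty: bool = False


@dataclass
class PotentialModel:
    """Trained conditional (per pair class) and reference distributions."""

    spec: RepresentationSpec
    config: TrainingConfig
    conditional: dict[PairKey, DistanceDistribution]
    reference: DistanceDistribution
    provenance: dict = field(default_factory=dict)

    # Scoring-grid cache: distributions truncated to score_cutoff, plus the
    # floored-uniform distribution used for unseen pair classes.
    _score_cache: Optional[dict] = field(default=None, repr=False, compare=False)

    def _scoring_tables(self) -> dict:
        if self._score_cache is None:
            cfg = self.config
            trunc = {
                key: dist.truncated(cfg.score_cutoff, cfg.probability_floor,
                                    cfg.renormalize_truncated)
                for key, dist in self.conditional.items()
            }
            reference = self.reference.truncated(
                cfg.score_cutoff, cfg.probability_floor,
                cfg.renormalize_truncated)
            unknown = fit_distribution([], cfg.score_cutoff, cfg)
            self._score_cache = {
                "conditional": trunc, "reference": reference,
                "unknown": unknown,
            }
        return self._score_cache

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Write the model as a self-describing JSON document."""
        def dist_dict(d: DistanceDistribution) -> dict:
            return {
                "cutoff": d.cutoff,
                "probs": d.probs.tolist(),
                "n_samples": d.n_samples,
                "bandwidth": d.bandwidth,
                "low_confidence": d.low_confidence,
            }

        doc = {
            "format": "pairpot-model",
            "format_version": MODEL_FORMAT_VERSION,
            "spec": asdict(self.spec),
            "config": asdict(self.config),
            "reference": dist_dict(self.reference),
            "conditional": {
                _key_str(key): dist_dict(dist)
                for key, dist in sorted(self.conditional.items())
            },
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "PotentialModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "pairpot-model":
            raise ValueError(f"{path}: not a pairpot model file")
        config = TrainingConfig(**doc["config"])

        def undist(d: dict) -> DistanceDistribution:
            n = config.n_bins(d["cutoff"])
            edges = np.linspace(0.0, d["cutoff"], n + 1)
            return DistanceDistribution(edges, np.array(d["probs"]),
                                        d["n_samples"], d["bandwidth"],
                                        d["low_confidence"])

        return cls(
            spec=RepresentationSpec(**doc["spec"]),
            config=config,
            conditional={_key_from_str(k): undist(v)
                         for k, v in doc["conditional"].items()},
            reference=undist(doc["reference"]),
            provenance=doc.get("provenance", {}),
        )


def _key_str(key: PairKey) -> str:
    (r1, l1), (r2, l2) = key
    return f"{r1}:{l1}|{r2}:{l2}"


def _key_from_str(s: str) -> PairKey:
    a, b = s.split("|")
    r1, l1 = a.split(":")
    r2, l2 = b.split(":")
    return ((r1, l1), (r2, l2))


def train(structures: Iterable[Chain], spec: RepresentationSpec,
          config: Optional[TrainingConfig] = None,
          provenance: Optional[dict] = None) -> PotentialModel:
    """Train a :class:`PotentialModel` from native chains.

    Conditional distributions pool observations per pair class across all
    chains at ``train_cutoff``; the reference pools observations from the
    prior representation given by ``spec.reference_mode``.
    """
    config = config or TrainingConfig()
    chains = list(structures)
    if not chains:
        raise ValueError("no training chains supplied")

    per_class: dict[PairKey, list[float]] = {}
    reference_samples: list[float] = []
    prior = spec.prior_spec()
    same_prior = prior == spec
    for chain in chains:
        sites = project(chain, spec)
        obs = collect_pairs(sites, config.train_cutoff, config.min_separation)
        for o in obs:
            per_class.setdefault(o.key, []).append(o.distance)
        if same_prior:
            reference_samples.extend(o.distance for o in obs)
        else:
            prior_sites = project(chain, prior)
            reference_samples.extend(
                o.distance for o in collect_pairs(
                    prior_sites, config.train_cutoff, config.min_separation))

    n_obs = sum(len(v) for v in per_class.values())
    if n_obs == 0:
        raise ValueError("no pair observations found in the training chains")

    # "global" scope: one shared bandwidth — the mean per-class Scott
    # estimate — applied to every distribution, reference included, so the
    # conditional and reference models are smoothed on the same scale.
    shared_bw: Optional[float] = None
    if config.bandwidth_scope == "global":
        per_class_bw = []
        for samples in per_class.values():
            try:
                per_class_bw.append(scott_bandwidth(samples))
            except DegenerateSamplesError:
                continue
        if per_class_bw:
            shared_bw = float(np.mean(per_class_bw))
    reference = fit_distribution(reference_samples, config.train_cutoff,
                                 config, bandwidth=shared_bw)
    conditional = {
        key: fit_distribution(samples, config.train_cutoff, config,
                              bandwidth=shared_bw)
        for key, samples in per_class.items()
    }

    meta = {
        "n_chains": len(chains),
        "n_observations": n_obs,
        "n_reference_observations": len(reference_samples),
        "n_classes": len(conditional),
        "format_version": MODEL_FORMAT_VERSION,
    }
    if provenance:
        meta.update(provenance)
    log.info("trained %s model: %d chains, %d observations, %d classes",
             spec.name, len(chains), n_obs, len(conditional))
    return PotentialModel(spec, config, conditional, reference, meta)


def _score(model: PotentialModel, chain: Chain, formalism: str,
           keep_terms: bool = False) -> ScoreResult:
    tables = model._scoring_tables()
    cfg = model.config
    sites = project(chain, model.spec)
    obs = collect_pairs(sites, cfg.score_cutoff, cfg.min_separation)
    if not obs:
        log.warning("chain %s yields no scorable pairs under %s",
                    chain.chain_id, model.spec.name)
        return ScoreResult(0.0, 0, [] if keep_terms else None, 0, empty=True)

    reference = tables["reference"]
    conditional = tables["conditional"]
    unknown = tables["unknown"]

    distances = np.array([o.distance for o in obs])
    bins = np.minimum((distances / reference.bin_width).astype(int),
                      len(reference.probs) - 1)
    p1 = np.empty(len(obs))
    n_unknown = 0
    for i, o in enumerate(obs):
        dist = conditional.get(o.key)
        if dist is None:
            dist = unknown
            n_unknown += 1
        p1[i] = dist.probs[bins[i]]
    ratio = p1 / reference.probs[bins]
    terms = -np.log(ratio) if formalism == "pmf" else -(ratio - 1.0)
    return ScoreResult(float(terms.sum()), len(obs),
                       terms.tolist() if keep_terms else None, n_unknown)


def score_pmf(model: PotentialModel, chain: Chain,
              keep_terms: bool = False) -> ScoreResult:
    """Negative log-likelihood-ratio score; lower = more native-like."""
    return _score(model, chain, "pmf", keep_terms)


def score_tig(model: PotentialModel, chain: Chain,
              keep_terms: bool = False) -> ScoreResult:
    """Relative-difference score, negated so lower = more native-like."""
    return _score(model, chain, "tig", keep_terms)


def information_gain(distance: float, key: PairKey,
                     model: PotentialModel) -> float:
    """Shannon surprisal drop from the reference to the conditional model.

    The PMF total over a chain equals the negated sum of these values over
    its scored pairs.
    """
    tables = model._scoring_tables()
    dist = tables["conditional"].get(key, tables["unknown"])
    p1 = dist.prob_at(distance)
    p2 = tables["reference"].prob_at(distance)
    return math.log(p1) - math.log(p2)
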