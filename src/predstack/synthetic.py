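"""Synthetic predictor-panel simulator.

Generates labeled proteins (sequence, per-site RSA, burial, amino-acid
class) and four simulated predictor outputs with controllable per-class
skill, confidence behaviour, and within-type correlation, so the whole
downstream pipeline is testable without any real model output.

Correlation mechanism: per site and per model type one shared latent
u ~ U(0,1) is drawn; each model of that type blends it with a fresh
uniform w into v = rho*u + (1-rho)*w and calls the site correctly iff
v < skill(class, burial). rho = 1 forces identical correctness coins
within a type, rho = 0 gives independent coins with exact marginals.

Every pseudo-random draw flows from one run seed through named substreams
keyed by (purpose, model_id, protein_id), so adding a model never perturbs
another model's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from predstack.alphabet import AA_TO_INDEX, CANONICAL_AA, N_AA
from predstack.errors import ConfigError
from predstack.evaluation import (
    DEFAULT_CLASS_MAP,
    accuracy_correlation,
    class_accuracy,
    per_protein_accuracies,
)
from predstack.formats_io import PredictionSet, SiteRecord

MODEL_TYPES = ("structure", "sequence")

#: Within-class confusion partner (a cycle inside each amino-acid class),
#: used by the "class_partner" decoy kernel.
CLASS_PARTNER: dict[str, str] = {
    "A": "V", "V": "L", "L": "I", "I": "M", "M": "A",
    "F": "W", "W": "Y", "Y": "F",
    "S": "T", "T": "N", "N": "Q", "Q": "C", "C": "S",
    "K": "R", "R": "H", "H": "K",
    "D": "E", "E": "D",
    "G": "P", "P": "G",
}


def substream(seed: int, *tokens: object) -> np.random.Generator:
    """Deterministic named substream of the run seed.

    Stable across processes (sha256 of the token tuple, not Python hash).
    """
    text = "\x1f".join(str(t) for t in tokens)
    digest = hashlib.sha256(text.encode("utf-8")).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([seed % 2**32, *words]))


def blend_cdf(s: float, rho: float) -> float:
    """P(rho*U + (1-rho)*W < s) for independent U, W ~ Uniform(0,1)."""
    a, b = max(rho, 1.0 - rho), min(rho, 1.0 - rho)
    s = float(np.clip(s, 0.0, 1.0))
    if b == 0.0:
        return s
    if s < b:
        return s * s / (2 * a * b)
    if s < a:
        return (s - b / 2) / a
    return 1.0 - (1.0 - s) ** 2 / (2 * a * b)


def blend_threshold(target: float, rho: float) -> float:
    """Skill threshold s with blend_cdf(s, rho) == target (exact inverse).

    Lets a config express per-cell *accuracy* targets independently of the
    correlation weight rho.
    """
    if not 0.0 <= target <= 1.0:
        raise ConfigError(f"target accuracy {target} outside [0,1]")
    a, b = max(rho, 1.0 - rho), min(rho, 1.0 - rho)
    if b == 0.0:
        return target
    if target < b / (2 * a):
        return float(np.sqrt(2 * a * b * target))
    if target <= 1.0 - b / (2 * a):
        return a * target + b / 2
    return 1.0 - float(np.sqrt(2 * a * b * (1.0 - target)))


def build_decoy_kernel(spec: Mapping[str, object]) -> np.ndarray:
    """Build a 20x20 row-stochastic decoy matrix with a zero diagonal.

    Row i is the distribution over wrong amino acids when the truth is
    amino acid i. Kinds:

    * ``{"kind": "uniform"}`` — uniform over the 19 others.
    * ``{"kind": "class_partner", "partner_weight": w}`` — mass w on the
      truth's within-class confusion partner, the rest uniform over the
      remaining 18.
    * ``{"kind": "matrix", "rows": ...}`` — explicit 20x20 rows.
    """
    kind = spec.get("kind")
    if kind == "uniform":
        kernel = np.full((N_AA, N_AA), 1.0 / (N_AA - 1))
        np.fill_diagonal(kernel, 0.0)
    elif kind == "class_partner":
        w = float(spec.get("partner_weight", 1.0))
        if not 0.0 <= w <= 1.0:
            raise ConfigError(f"partner_weight must be in [0,1], got {w}")
        # mass w on the partner, the rest uniform over the other 18
        kernel = np.full((N_AA, N_AA), (1.0 - w) / (N_AA - 2))
        np.fill_diagonal(kernel, 0.0)
        for aa, partner in CLASS_PARTNER.items():
            kernel[AA_TO_INDEX[aa], AA_TO_INDEX[partner]] = w
    elif kind == "matrix":
        kernel = np.asarray(spec["rows"], dtype=float)
    else:
        raise ConfigError(f"unknown decoy kernel kind {kind!r}")

    if kernel.shape != (N_AA, N_AA):
        raise ConfigError(f"decoy kernel must be {N_AA}x{N_AA}")
    if np.any(np.diagonal(kernel) != 0):
        raise ConfigError("decoy kernel must assign 0 to the true amino acid")
    if np.any(kernel < 0) or not np.allclose(kernel.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigError("decoy kernel rows must be distributions")
    return kernel


@dataclass
class SkillProfile:
    """One simulated predictor.

    skill maps (aa_class, burial) to the probability of a correct call;
    confidence (the top probability emitted) is Beta-distributed, with
    separate parameters for correct and wrong calls; decoy_spec describes
    the distribution of wrong top predictions (see build_decoy_kernel).
    """

    model_id: str
    model_type: str
    skill: dict[tuple[str, str], float]
    confidence_when_correct: tuple[float, float] = (9.0, 3.0)
    confidence_when_wrong: tuple[float, float] = (4.0, 6.0)
    decoy_spec: dict = field(default_factory=lambda: {"kind": "uniform"})

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ConfigError(f"model_type must be one of {MODEL_TYPES}")
        for key, value in self.skill.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"skill{key} = {value} outside [0,1]")
        for name, (a, b) in (("confidence_when_correct", self.confidence_when_correct),
                             ("confidence_when_wrong", self.confidence_when_wrong)):
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name} Beta parameters must be > 0")
        build_decoy_kernel(self.decoy_spec)  # validates

    def decoy_kernel(self) -> np.ndarray:
        return build_decoy_kernel(self.decoy_spec)


@dataclass
class PanelConfig:
    """Full configuration of a four-predictor synthetic panel."""

    profiles: list[SkillProfile]
    rho_within_type: dict[str, float]
    burial_threshold: float = 0.2
    rsa_mixture_weights: tuple[float, ...] = (0.45, 0.55)
    rsa_mixture_alphas: tuple[float, ...] = (1.5, 4.0)
    rsa_mixture_betas: tuple[float, ...] = (10.0, 3.0)
    composition: dict[str, np.ndarray] = field(default_factory=dict)
    protein_length_range: tuple[int, int] = (100, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.profiles) != 4:
            raise ConfigError(f"need exactly 4 profiles, got {len(self.profiles)}")
        by_type = {t: [p for p in self.profiles if p.model_type == t] for t in MODEL_TYPES}
        if any(len(v) != 2 for v in by_type.values()):
            raise ConfigError("need exactly two structure-type and two sequence-type profiles")
        if len({p.model_id for p in self.profiles}) != 4:
            raise ConfigError("model ids must be distinct")
        for t in MODEL_TYPES:
            rho = self.rho_within_type.get(t)
            if rho is None or not 0.0 <= rho <= 1.0:
                raise ConfigError(f"rho_within_type[{t!r}] must be in [0,1]")
        weights = np.asarray(self.rsa_mixture_weights, dtype=float)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-9):
            raise ConfigError("rsa_mixture weights must be nonnegative and sum to 1")
        if len(self.rsa_mixture_alphas) != len(weights) or len(self.rsa_mixture_betas) != len(weights):
            raise ConfigError("rsa_mixture component count mismatch")
        for burial in ("buried", "exposed"):
            comp = np.asarray(self.composition.get(burial, ()), dtype=float)
            if comp.shape != (N_AA,) or np.any(comp < 0) or not np.isclose(comp.sum(), 1.0, atol=1e-9):
                raise ConfigError(f"composition[{burial!r}] must be a 20-way distribution")
            self.composition[burial] = comp
        lo, hi = self.protein_length_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"bad protein_length_range {self.protein_length_range}")

    def structure_ids(self) -> list[str]:
        return sorted(p.model_id for p in self.profiles if p.model_type == "structure")

    def sequence_ids(self) -> list[str]:
        return sorted(p.model_id for p in self.profiles if p.model_type == "sequence")

    def model_types(self) -> dict[str, str]:
        return {p.model_id: p.model_type for p in self.profiles}


def _skill_table(buried: Mapping[str, float], exposed: Mapping[str, float],
                 offset: float, rho: float) -> dict[tuple[str, str], float]:
    """Skill thresholds from per-cell target accuracies at blend weight rho."""
    table = {}
    for burial, targets in (("buried", buried), ("exposed", exposed)):
        for cls, v in targets.items():
            target = float(np.clip(v + offset, 0.02, 0.98))
            table[(cls, burial)] = blend_threshold(target, rho)
    return table


# Type-level class x burial accuracy targets for the default panel:
# structure models strongest on buried aliphatic/unique sites, sequence
# models on polar/charged sites; every model's accuracy declines with
# exposure so mean confidence declines with RSA.
_STRUCT_BURIED = {"aliphatic": 0.85, "unique": 0.82, "aromatic": 0.75,
                  "polar": 0.60, "positive": 0.55, "negative": 0.55}
_STRUCT_EXPOSED = {"aliphatic": 0.60, "unique": 0.58, "aromatic": 0.55,
                   "polar": 0.45, "positive": 0.42, "negative": 0.42}
_SEQ_BURIED = {"aliphatic": 0.62, "unique": 0.56, "aromatic": 0.68,
               "polar": 0.74, "positive": 0.75, "negative": 0.75}
_SEQ_EXPOSED = {"aliphatic": 0.55, "unique": 0.50, "aromatic": 0.62,
                "polar": 0.70, "positive": 0.70, "negative": 0.70}

_BURIED_COMPOSITION = {
    "A": .10, "C": .03, "D": .02, "E": .02, "F": .06, "G": .08, "H": .02,
    "I": .09, "K": .01, "L": .13, "M": .04, "N": .02, "P": .03, "Q": .02,
    "R": .02, "S": .04, "T": .04, "V": .11, "W": .04, "Y": .08,
}
_EXPOSED_COMPOSITION = {
    "A": .05, "C": .01, "D": .08, "E": .10, "F": .02, "G": .06, "H": .03,
    "I": .03, "K": .09, "L": .05, "M": .01, "N": .06, "P": .05, "Q": .06,
    "R": .07, "S": .08, "T": .07, "V": .04, "W": .01, "Y": .03,
}


def _composition_vector(freqs: Mapping[str, float]) -> np.ndarray:
    v = np.array([freqs[aa] for aa in CANONICAL_AA], dtype=float)
    return v / v.sum()


def default_panel_config(seed: int = 0) -> PanelConfig:
    """Default panel: calibration near the documented per-model means.

    Mean per-model accuracies land near 0.61/0.64/0.65/0.68; within-type
    accuracy correlation is strong for the structure pair and moderate for
    the sequence pair; cross-type correlation is near zero.
    """
    decoy = {"kind": "class_partner", "partner_weight": 0.7}
    rho = {"structure": 0.8, "sequence": 0.55}
    profiles = [
        SkillProfile("struct_a", "structure",
                     _skill_table(_STRUCT_BURIED, _STRUCT_EXPOSED, 0.05, rho["structure"]),
                     decoy_spec=dict(decoy)),
        SkillProfile("struct_b", "structure",
                     _skill_table(_STRUCT_BURIED, _STRUCT_EXPOSED, 0.06, rho["structure"]),
                     decoy_spec=dict(decoy)),
        SkillProfile("seq_a", "sequence",
                     _skill_table(_SEQ_BURIED, _SEQ_EXPOSED, -0.04, rho["sequence"]),
                     decoy_spec=dict(decoy)),
        SkillProfile("seq_b", "sequence",
                     _skill_table(_SEQ_BURIED, _SEQ_EXPOSED, 0.03, rho["sequence"]),
                     decoy_spec=dict(decoy)),
    ]
    return PanelConfig(
        profiles=profiles,
        rho_within_type=rho,
        composition={"buried": _composition_vector(_BURIED_COMPOSITION),
                     "exposed": _composition_vector(_EXPOSED_COMPOSITION)},
        seed=seed,
    )


def complementary_panel_config(seed: int = 0) -> PanelConfig:
    """Panel with fully complementary skills for the stacking-dominance check.

    Structure-type models: skill 0.9 on buried sites, 0.3 on exposed;
    sequence-type models the reverse. Buried and exposed sites draw from
    disjoint amino-acid pools, decoys are the deterministic within-class
    partner, and confidence carries no information about correctness, so
    naive averaging and max-voting cannot separate truth from the decoy
    while a trained stack can.
    """
    struct_skill = {(c, "buried"): 0.9 for c in DEFAULT_CLASS_MAP.values()}
    struct_skill |= {(c, "exposed"): 0.3 for c in DEFAULT_CLASS_MAP.values()}
    seq_skill = {(c, "buried"): 0.3 for c in DEFAULT_CLASS_MAP.values()}
    seq_skill |= {(c, "exposed"): 0.9 for c in DEFAULT_CLASS_MAP.values()}
    conf = (10.0, 4.0)
    decoy = {"kind": "class_partner", "partner_weight": 1.0}
    profiles = [
        SkillProfile("struct_a", "structure", dict(struct_skill), conf, conf, dict(decoy)),
        SkillProfile("struct_b", "structure", dict(struct_skill), conf, conf, dict(decoy)),
        SkillProfile("seq_a", "sequence", dict(seq_skill), conf, conf, dict(decoy)),
        SkillProfile("seq_b", "sequence", dict(seq_skill), conf, conf, dict(decoy)),
    ]
    buried_pool = [aa for aa in CANONICAL_AA
                   if DEFAULT_CLASS_MAP[aa] in ("aliphatic", "aromatic", "unique")]
    exposed_pool = [aa for aa in CANONICAL_AA
                    if DEFAULT_CLASS_MAP[aa] in ("polar", "positive", "negative")]
    buried = np.zeros(N_AA)
    buried[[AA_TO_INDEX[a] for a in buried_pool]] = 1.0 / len(buried_pool)
    exposed = np.zeros(N_AA)
    exposed[[AA_TO_INDEX[a] for a in exposed_pool]] = 1.0 / len(exposed_pool)
    return PanelConfig(
        profiles=profiles,
        rho_within_type={"structure": 0.8, "sequence": 0.8},
        rsa_mixture_weights=(0.5, 0.5),
        rsa_mixture_alphas=(1.2, 6.0),
        rsa_mixture_betas=(12.0, 2.5),
        composition={"buried": buried, "exposed": exposed},
        protein_length_range=(150, 150),
        seed=seed,
    )


def _sample_rsa(config: PanelConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.asarray(config.rsa_mixture_weights, dtype=float)
    comp = rng.choice(len(weights), size=n, p=weights)
    rsa = np.empty(n)
    for k in range(len(weights)):
        mask = comp == k
        if not mask.any():
            continue
        a, b = config.rsa_mixture_alphas[k], config.rsa_mixture_betas[k]
        if a < 0 or b < 0 or (a == 0 and b == 0):
            raise ConfigError(f"degenerate rsa_mixture component {k}: alpha={a}, beta={b}")
        if a == 0:
            rsa[mask] = 0.0  # point mass at fully buried
        elif b == 0:
            rsa[mask] = 1.0  # point mass at fully exposed
        else:
            rsa[mask] = rng.beta(a, b, mask.sum())
    return rsa


def generate_protein(
    config: PanelConfig,
    protein_id: str,
    length: int,
    rng: np.random.Generator | int,
) -> tuple[str, list[SiteRecord]]:
    """Draw one labeled protein: sequence plus per-site RSA/burial/class."""
    if isinstance(rng, int):
        rng = substream(rng, "protein", protein_id)
    lo, hi = config.protein_length_range
    if not lo <= length <= hi:
        raise ConfigError(f"length {length} outside protein_length_range {config.protein_length_range}")
    rsa = _sample_rsa(config, length, rng)
    buried = rsa < config.burial_threshold
    wt_idx = np.empty(length, dtype=int)
    for burial, mask in (("buried", buried), ("exposed", ~buried)):
        if mask.any():
            wt_idx[mask] = rng.choice(N_AA, size=int(mask.sum()),
                                      p=config.composition[burial])
    sites = []
    for i in range(length):
        aa = CANONICAL_AA[wt_idx[i]]
        sites.append(SiteRecord(protein_id, i + 1, aa, float(rsa[i]),
                                DEFAULT_CLASS_MAP[aa]))
    sequence = "".join(CANONICAL_AA[j] for j in wt_idx)
    return sequence, sites


def simulate_predictor(
    sites: Sequence[SiteRecord],
    profile: SkillProfile,
    shared_latents: np.ndarray,
    rho: float,
    rng: np.random.Generator | int,
    burial_threshold: float = 0.2,
) -> np.ndarray:
    """Simulate one model's 20-way vectors for a list of sites.

    Returns an (n_sites, 20) array. Correct calls place Beta-distributed
    confidence on the wildtype; wrong calls place it on a decoy drawn from
    the profile's decoy kernel; the remaining mass is uniform over the
    other 19 amino acids.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    n = len(sites)
    shared_latents = np.asarray(shared_latents, dtype=float)
    if shared_latents.shape != (n,):
        raise ConfigError(f"need one shared latent per site ({n}), got {shared_latents.shape}")

    wt_idx = np.empty(n, dtype=int)
    skill = np.empty(n)
    for i, site in enumerate(sites):
        wt_idx[i] = AA_TO_INDEX[site.wt_aa]
        cls = site.aa_class or DEFAULT_CLASS_MAP[site.wt_aa]
        burial = "buried" if (site.rsa is not None and site.rsa < burial_threshold) else "exposed"
        try:
            skill[i] = profile.skill[(cls, burial)]
        except KeyError:
            raise ConfigError(
                f"profile {profile.model_id!r} missing skill cell ({cls!r}, {burial!r})"
            ) from None

    fresh = rng.random(n)
    v = rho * shared_latents + (1.0 - rho) * fresh
    correct = v < skill
    conf_correct = rng.beta(*profile.confidence_when_correct, size=n)
    conf_wrong = rng.beta(*profile.confidence_when_wrong, size=n)
    decoy_u = rng.random(n)

    kernel = profile.decoy_kernel()
    cumulative = np.cumsum(kernel, axis=1)
    decoy_idx = (cumulative[wt_idx] > decoy_u[:, None]).argmax(axis=1)

    conf = np.where(correct, conf_correct, conf_wrong)
    top_idx = np.where(correct, wt_idx, decoy_idx)
    vectors = np.repeat(((1.0 - conf) / (N_AA - 1))[:, None], N_AA, axis=1)
    vectors[np.arange(n), top_idx] = conf
    return vectors


def simulate_panel(
    config: PanelConfig,
    n_proteins: int,
    seed: int | None = None,
) -> tuple[PredictionSet, list[SiteRecord]]:
    """Simulate the full four-model panel over n_proteins proteins.

    Deterministic for a fixed seed. Models of the same type share per-site
    latents with weight rho_within_type[type]; there is no sharing across
    types.
    """
    if n_proteins < 1:
        raise ConfigError(f"n_proteins must be >= 1, got {n_proteins}")
    seed = config.seed if seed is None else seed
    pset = PredictionSet(model_ids=[p.model_id for p in config.profiles])
    labels: list[SiteRecord] = []
    width = max(5, len(str(n_proteins)))
    for i in range(n_proteins):
        pid = f"P{i:0{width}d}"
        rng_protein = substream(seed, "protein", pid)
        lo, hi = config.protein_length_range
        length = int(rng_protein.integers(lo, hi + 1))
        _, sites = generate_protein(config, pid, length, rng_protein)
        latents = {t: substream(seed, "latent", t, pid).random(length)
                   for t in MODEL_TYPES}
        for profile in config.profiles:
            rng_model = substream(seed, "model", profile.model_id, pid)
            vectors = simulate_predictor(
                sites, profile, latents[profile.model_type],
                config.rho_within_type[profile.model_type], rng_model,
                config.burial_threshold,
            )
            for site, vec in zip(sites, vectors):
                pset.entries[(pid, site.position, profile.model_id)] = vec
        labels.extend(sites)
    return pset, labels


@dataclass
class PanelSummary:
    """Calibration readout of an achieved panel."""

    overall_accuracy: dict[str, float]
    per_protein_accuracy: dict[str, dict[str, float]]
    correlation: dict[tuple[str, str], tuple[float, float]]
    per_class_accuracy: dict[str, dict[str, float]]


def panel_summary(pset: PredictionSet, labels: Sequence[SiteRecord]) -> PanelSummary:
    """Achieved accuracies, pairwise correlations, and class accuracies."""
    import warnings

    overall: dict[str, float] = {}
    per_protein: dict[str, dict[str, float]] = {}
    for mid in pset.model_ids:
        accs = per_protein_accuracies(pset, labels, mid)
        per_protein[mid] = {p: a.fraction for p, a in accs.items()}
        n_correct = sum(a.n_correct for a in accs.values())
        n_total = sum(a.n_sites for a in accs.values())
        overall[mid] = n_correct / n_total if n_total else float("nan")

    correlation: dict[tuple[str, str], tuple[float, float]] = {}
    proteins = sorted({s.protein_id for s in labels})
    for i, ma in enumerate(pset.model_ids):
        for mb in pset.model_ids[i + 1:]:
            if len(proteins) < 3:
                warnings.warn("fewer than 3 proteins: correlations undefined")
                correlation[(ma, mb)] = (float("nan"), float("nan"))
                continue
            va = [per_protein[ma][p] for p in proteins]
            vb = [per_protein[mb][p] for p in proteins]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                correlation[(ma, mb)] = accuracy_correlation(va, vb)

    per_class = {
        mid: {c: a.fraction for c, a in class_accuracy(pset, labels, mid).items()}
        for mid in pset.model_ids
    }
    return PanelSummary(overall, per_protein, correlation, per_class)


# ---------------------------------------------------------------------------
# Config (de)serialization

def panel_config_to_dict(config: PanelConfig) -> dict:
    return {
        "profiles": [
            {
                "model_id": p.model_id,
                "model_type": p.model_type,
                "skill": {f"{cls}/{burial}": v for (cls, burial), v in sorted(p.skill.items())},
                "confidence_when_correct": list(p.confidence_when_correct),
                "confidence_when_wrong": list(p.confidence_when_wrong),
                "decoy": dict(p.decoy_spec),
            }
            for p in config.profiles
        ],
        "rho_within_type": dict(config.rho_within_type),
        "burial_threshold": config.burial_threshold,
        "rsa_mixture": {
            "weights": list(config.rsa_mixture_weights),
            "alphas": list(config.rsa_mixture_alphas),
            "betas": list(config.rsa_mixture_betas),
        },
        "composition": {k: [float(x) for x in v] for k, v in config.composition.items()},
        "protein_length_range": list(config.protein_length_range),
        "seed": config.seed,
    }


def panel_config_from_dict(data: Mapping) -> PanelConfig:
    try:
        profiles = [
            SkillProfile(
                model_id=p["model_id"],
                model_type=p["model_type"],
                skill={(k.split("/")[0], k.split("/")[1]): float(v)
                       for k, v in p["skill"].items()},
                confidence_when_correct=tuple(p.get("confidence_when_correct", (9.0, 3.0))),
                confidence_when_wrong=tuple(p.get("confidence_when_wrong", (4.0, 6.0))),
                decoy_spec=dict(p.get("decoy", {"kind": "uniform"})),
            )
            for p in data["profiles"]
        ]
        mixture = data.get("rsa_mixture", {})
        return PanelConfig(
            profiles=profiles,
            rho_within_type=dict(data["rho_within_type"]),
            burial_threshold=float(data.get("burial_threshold", 0.2)),
            rsa_mixture_weights=tuple(mixture.get("weights", (0.45, 0.55))),
            rsa_mixture_alphas=tuple(mixture.get("alphas", (1.5, 4.0))),
            rsa_mixture_betas=tuple(mixture.get("betas", (10.0, 3.0))),
            composition={k: np.asarray(v, dtype=float)
                         for k, v in data["composition"].items()},
            protein_length_range=tuple(data.get("protein_length_range", (100, 200))),
            seed=int(data.get("seed", 0)),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise ConfigError(f"malformed panel config: {exc}") from exc


def save_panel_config(config: PanelConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(panel_config_to_dict(config), fh, sort_keys=False)


def load_panel_config(path: str | Path) -> PanelConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: not a mapping")
    return panel_config_from_dict(data)
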