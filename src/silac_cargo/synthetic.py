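"""Synthetic SILAC quantification tables with planted cargo structure.

The generator emulates the protein-level ratio tables a search engine would
export from a reconstituted nuclear-import experiment, downstream of all
spectral processing:

- each protein has a log-normal abundance and a protein-specific baseline
  log2 L/H ratio;
- each run adds independent Gaussian measurement noise on the log2 scale
  (optionally plus a per-run global shift, which the within-replicate
  Z-normalization is designed to absorb);
- planted cargoes of a receptor get an import effect delta (log2 units,
  truncated normal) added in the +NTR condition only;
- the L/H count is Poisson with mean affine in abundance, and a protein is
  absent from a run when its drawn count is zero or it drops out (dropout
  probability decreasing with abundance) — reproducing the
  missing-counterpart structure that the pairing rule discards. The default
  count and dropout parameters are calibrated so that roughly four proteins
  are quantified in all three replicate pairs for every one quantified in
  only two, matching the replicate structure of real screens of this kind.

"Reported" labels are drawn from planted cargoes only, so evaluation
positives are true by construction; localization labels make the
non-nuclear negative definition exercisable. One control run is generated
per replicate and shared by all receptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, UsageError
from .io import AnnotationSet, Condition, Localization, QuantRecord, QuantRun
from .ranking import CargoSet

__all__ = ["SimulationConfig", "SyntheticTruth", "RecoveryStats", "generate", "recovery_report"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Defaults emulate the scale of the real screens: ~2000 quantified
    proteins per receptor, 12 receptors, 3 replicates. ``effect_log2`` is
    the planted import effect on log2(+NTR/Ctl) for cargoes; ``noise_log2``
    the per-run measurement noise sd of X. ``sharing_design`` lists
    (receptor_a, receptor_b, fraction) triples: receptor_b's cargo set
    reuses that fraction of receptor_a's.
    """

    n_proteins: int = 2000
    n_receptors: int = 12
    n_replicates: int = 3
    cargo_fraction: float = 0.08
    sharing_design: tuple[tuple[str, str, float], ...] = ()
    effect_mean_log2: float = 1.5
    effect_sd_log2: float = 0.5
    effect_min_log2: float = 0.3
    noise_log2: float = 0.6
    baseline_sd_log2: float = 0.5
    abundance_mu: float = 0.0      # ln-scale location of the log-normal
    abundance_sigma: float = 1.0   # ln-scale spread
    count_floor: float = 4.0       # baseline expected L/H count at vanishing abundance
    count_scale: float = 5.0       # additional expected L/H count per unit abundance
    dropout: float = 0.08
    replicate_shift_sd: float = 0.0
    reported_fraction: float = 0.1
    nonnuclear_fraction: float = 0.15
    seed: int = 0
    receptor_names: tuple[str, ...] = ()

    def validate(self) -> None:
        bad = []
        if self.n_proteins < 10:
            bad.append("n_proteins")
        if self.n_receptors < 1:
            bad.append("n_receptors")
        if self.n_replicates not in (2, 3):
            bad.append("n_replicates")
        for name in ("cargo_fraction", "dropout", "reported_fraction", "nonnuclear_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(name)
        for name in ("effect_sd_log2", "noise_log2", "baseline_sd_log2",
                     "abundance_sigma", "count_floor", "count_scale", "replicate_shift_sd"):
            if getattr(self, name) < 0:
                bad.append(name)
        if self.receptor_names and len(self.receptor_names) != self.n_receptors:
            bad.append("receptor_names")
        for a, b, frac in self.sharing_design:
            if not 0.0 <= frac <= 1.0:
                bad.append(f"sharing_design[{a},{b}]")
        if bad:
            raise ConfigError(f"invalid configuration field(s): {', '.join(bad)}")

    def receptors(self) -> tuple[str, ...]:
        if self.receptor_names:
            return self.receptor_names
        return tuple(f"NTR-{i + 1:02d}" for i in range(self.n_receptors))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth sufficient to recompute expectations of the tables."""

    cargoes: dict[str, dict[str, float]]  # receptor -> {accession: delta_log2}
    abundance: dict[str, float]
    baseline_log2: dict[str, float]
    localization: dict[str, Localization]
    reported: dict[str, set[str]]
    seed: int


@dataclass(frozen=True)
class RecoveryStats:
    receptor: str
    n_planted: int
    n_called: int
    n_recovered: int
    recall: float
    precision: float


def _draw_effects(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Truncated-normal import effects (resampling below the floor)."""
    out = rng.normal(cfg.effect_mean_log2, cfg.effect_sd_log2, size=n)
    if cfg.effect_sd_log2 == 0:
        return np.maximum(out, cfg.effect_min_log2)
    for _ in range(1000):
        low = out < cfg.effect_min_log2
        if not low.any():
            break
        out[low] = rng.normal(cfg.effect_mean_log2, cfg.effect_sd_log2, size=int(low.sum()))
    return np.maximum(out, cfg.effect_min_log2)


def generate(config: SimulationConfig) -> tuple[list[QuantRun], SyntheticTruth, AnnotationSet]:
    """Generate quantification runs, ground truth, and annotation.

    Returns one control run per replicate (receptor ``None``) plus one +NTR
    run per receptor and replicate. Identical config (including seed) gives
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accessions = [f"SYN{i:05d}" for i in range(n)]
    receptors = config.receptors()

    abundance = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=n)
    baseline = rng.normal(0.0, config.baseline_sd_log2, size=n)

    # Plant cargo sets, honoring the sharing design.
    n_cargo = max(1, round(config.cargo_fraction * n)) if config.cargo_fraction > 0 else 0
    share_map = {b: (a, frac) for a, b, frac in config.sharing_design}
    cargoes: dict[str, dict[str, float]] = {}
    cargo_indices: dict[str, np.ndarray] = {}
    for receptor in receptors:
        if n_cargo == 0:
            cargoes[receptor] = {}
            cargo_indices[receptor] = np.array([], dtype=int)
            continue
        if receptor in share_map and share_map[receptor][0] in cargo_indices:
            partner, frac = share_map[receptor]
            n_shared = round(frac * n_cargo)
            shared = rng.choice(cargo_indices[partner], size=min(n_shared, len(cargo_indices[partner])), replace=False)
            pool = np.setdiff1d(np.arange(n), shared)
            fresh = rng.choice(pool, size=n_cargo - len(shared), replace=False)
            idx = np.concatenate([shared, fresh])
        else:
            idx = rng.choice(n, size=n_cargo, replace=False)
        idx = np.sort(idx)
        deltas = _draw_effects(rng, len(idx), config)
        cargo_indices[receptor] = idx
        cargoes[receptor] = {accessions[i]: float(d) for i, d in zip(idx, deltas)}

    # Annotation: reported labels from planted cargoes; localization labels.
    reported: dict[str, set[str]] = {}
    for receptor in receptors:
        members = sorted(cargoes[receptor])
        if members:
            k = max(1, round(config.reported_fraction * len(members)))
            chosen = rng.choice(len(members), size=min(k, len(members)), replace=False)
            reported[receptor] = {members[i] for i in chosen}
        else:
            reported[receptor] = set()
    any_cargo = set().union(*(set(c) for c in cargoes.values())) if cargoes else set()
    localization: dict[str, Localization] = {}
    u = rng.random(n)
    for i, acc in enumerate(accessions):
        if acc in any_cargo:
            localization[acc] = Localization.NUCLEAR
        elif u[i] < config.nonnuclear_fraction:
            localization[acc] = Localization.NON_NUCLEAR
        elif u[i] < config.nonnuclear_fraction + (1 - config.nonnuclear_fraction) / 2:
            localization[acc] = Localization.NUCLEAR
        else:
            localization[acc] = Localization.UNDETERMINED

    lam = config.count_floor + config.count_scale * abundance
    p_drop = config.dropout / (1.0 + abundance)

    def draw_run(receptor: str | None, condition: Condition, replicate: int) -> QuantRun:
        counts = rng.poisson(lam)
        dropped = rng.random(n) < p_drop
        noise = rng.normal(0.0, config.noise_log2, size=n)
        shift = rng.normal(0.0, config.replicate_shift_sd) if config.replicate_shift_sd > 0 else 0.0
        log2lh = baseline + shift + noise
        if condition is Condition.NTR:
            for i in cargo_indices[receptor]:
                log2lh[i] += cargoes[receptor][accessions[i]]
        records = {
            accessions[i]: QuantRecord(lh_ratio=float(2.0 ** log2lh[i]), lh_count=int(counts[i]))
            for i in range(n)
            if counts[i] >= 1 and not dropped[i]
        }
        return QuantRun(receptor=receptor, condition=condition, replicate=replicate, records=records)

    runs: list[QuantRun] = []
    for replicate in range(1, config.n_replicates + 1):
        runs.append(draw_run(None, Condition.CTL, replicate))
    for receptor in receptors:
        for replicate in range(1, config.n_replicates + 1):
            runs.append(draw_run(receptor, Condition.NTR, replicate))

    truth = SyntheticTruth(
        cargoes=cargoes,
        abundance={acc: float(a) for acc, a in zip(accessions, abundance)},
        baseline_log2={acc: float(b) for acc, b in zip(accessions, baseline)},
        localization=localization,
        reported=reported,
        seed=config.seed,
    )
    annotations = AnnotationSet(
        reported={r: set(s) for r, s in reported.items()},
        localization=dict(localization),
    )
    return runs, truth, annotations


def recovery_report(truth: SyntheticTruth, cargo_sets: Sequence[CargoSet]) -> dict[str, RecoveryStats]:
    """Recall and precision of called cargo sets against the planted truth."""
    out = {}
    for cs in cargo_sets:
        if cs.receptor not in truth.cargoes:
            raise UsageError(f"receptor {cs.receptor!r} not present in the synthetic truth")
        planted = set(truth.cargoes[cs.receptor])
        called = set(cs.members)
        recovered = planted & called
        out[cs.receptor] = RecoveryStats(
            receptor=cs.receptor,
            n_planted=len(planted),
            n_called=len(called),
            n_recovered=len(recovered),
            recall=len(recovered) / len(planted) if planted else 0.0,
            precision=len(recovered) / len(called) if called else 0.0,
        )
    return out
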