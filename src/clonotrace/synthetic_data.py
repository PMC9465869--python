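"""Synthetic longitudinal repertoires and proliferation assays with ground truth.

Real bulk TRB repertoires are heavy-tailed: a handful of large clones plus a
long tail of rare ones.  The generator models clone frequencies with a Zipf
power law (frequency of the rank-r clone proportional to r**-a), draws read
counts multinomially at a configured depth, and builds one patient's sample
set:

* baseline PBMC (vaccine-reactive clones absent by construction, so the
  baseline filter has known positives),
* week-7 unstimulated and 10-day-stimulated PBMC (the stimulated sample
  multiplies the spiked clones' frequencies by a known fold, then
  renormalizes),
* a later PBMC sample (week 18) with configurable clone persistence,
* baseline and post-treatment tumor biopsies sharing a configurable
  fraction of blood clones, the post-treatment biopsy carrying the spiked
  clones at low frequency.

Triplicate proliferation counts are drawn log-normally around a base mean
with a configured coefficient of variation; stimulated-well means are the
base mean times the true stimulation index, so the SI estimator can be
checked for parameter recovery.

Everything is reproducible from the config seed.  The generator emulates
the statistical structure of repertoire data only — no V(D)J recombination,
sequencing-error or PCR-bias modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .immune_response import PEPTIDES, ProliferationAssay
from .repertoire_io import (
    CloneRecord,
    Compartment,
    Repertoire,
    SampleMeta,
    Stimulation,
)

__all__ = [
    "SimConfig",
    "SAMPLE_LABELS",
    "zipf_frequencies",
    "random_cdr3s",
    "simulate_patient",
    "simulate_assays",
]

#: Labels of the samples one simulated patient yields, in canonical order.
SAMPLE_LABELS = (
    "pbmc_baseline",
    "pbmc_week7_unstim",
    "pbmc_week7_stim",
    "pbmc_week18",
    "tumor_baseline",
    "tumor_post",
)

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for one simulated patient.

    Defaults describe a realistic bulk TRB library: 5,000 clones, Zipf
    exponent 1.0, 50,000 reads per sample, 80% clone persistence between
    consecutive timepoints, 20% blood->tumor sharing, 5 vaccine-reactive
    clones at frequency 1e-3 each that expand 64-fold under 10-day
    stimulation, and 10% replicate noise around a true SI.
    """

    n_clones: int = 5000
    zipf_exponent: float = 1.0
    depth: int = 50_000
    persistence: float = 0.8
    tumor_share: float = 0.2
    n_spike: int = 5
    spike_fold: float = 64.0
    spike_freq: float = 1e-3
    si_true: float = 10.0
    noise_cv: float = 0.1
    seed: int = 0
    patient_id: str = "SIM01"
    #: Fraction of n_clones added as tumor-private clones per biopsy.
    tumor_private_frac: float = 0.1
    #: Mean counts-per-minute of unstimulated wells in the assay generator.
    base_cpm: float = 1000.0
    #: Deliberately seed the spiked clones into baseline PBMC (to test that
    #: the baseline filter removes them); off by default.
    leak_spikes_into_baseline: bool = False

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for name in ("persistence", "tumor_share", "tumor_private_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_spike < 0:
            raise ValueError("n_spike must be >= 0")
        if self.spike_fold < 1:
            raise ValueError("spike_fold must be >= 1")
        if not 0.0 < self.spike_freq < 1.0 and self.n_spike > 0:
            raise ValueError("spike_freq must be in (0, 1)")
        if self.n_spike * self.spike_freq >= 0.5:
            raise ValueError("total spike frequency must stay below 0.5")
        if self.si_true <= 0:
            raise ValueError("si_true must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def zipf_frequencies(n: int, exponent: float) -> np.ndarray:
    """Normalized power-law clone frequencies: f_r proportional to r**-exponent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    weights = np.arange(1, n + 1, dtype=np.float64) ** -exponent
    return weights / weights.sum()


def random_cdr3s(n: int, rng: np.random.Generator) -> list[str]:
    """``n`` unique domain-plausible CDR3s: 'CASS' + 4-10 residues + 'F'."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(4, 11))
        core = "".join(rng.choice(_AA20, size=length))
        cdr3 = f"CASS{core}F"
        if cdr3 not in seen:
            seen.add(cdr3)
            out.append(cdr3)
    return out


def _draw(
    meta: SampleMeta,
    keys: Sequence[str],
    freqs: np.ndarray,
    depth: int,
    rng: np.random.Generator,
) -> Repertoire:
    """Multinomial read draw at ``depth`` from normalized frequencies."""
    freqs = np.asarray(freqs, dtype=np.float64)
    freqs = freqs / freqs.sum()
    counts = rng.multinomial(depth, freqs)
    clones = {
        k: CloneRecord(cdr3_aa=k, count=int(c))
        for k, c in zip(keys, counts)
        if c > 0
    }
    return Repertoire(meta=meta, clones=clones)


def simulate_patient(
    config: SimConfig,
) -> tuple[dict[str, Repertoire], pd.DataFrame]:
    """Generate one patient's six samples plus the spike ground truth.

    Returns ``(samples, truth)`` where ``samples`` maps each label in
    :data:`SAMPLE_LABELS` to a :class:`Repertoire` and ``truth`` has one
    row per spiked (vaccine-reactive) clone: its CDR3, its pre-stimulation
    frequency and its true stimulation fold change.
    """
    rng = np.random.default_rng(config.seed)
    n_private = max(1, int(round(config.n_clones * config.tumor_private_frac)))
    pool = random_cdr3s(config.n_clones + config.n_spike + 2 * n_private, rng)
    base_keys = pool[: config.n_clones]
    spike_keys = pool[config.n_clones : config.n_clones + config.n_spike]
    priv_base = pool[config.n_clones + config.n_spike :
                     config.n_clones + config.n_spike + n_private]
    priv_post = pool[config.n_clones + config.n_spike + n_private :]

    base_freq = zipf_frequencies(config.n_clones, config.zipf_exponent)
    spike_total = config.n_spike * config.spike_freq
    pid = config.patient_id

    def pbmc_meta(timepoint: str, stim: Stimulation = Stimulation.UNSTIMULATED):
        return SampleMeta(pid, timepoint, Compartment.PBMC, stim)

    def tumor_meta(timepoint: str):
        return SampleMeta(pid, timepoint, Compartment.TUMOR)

    samples: dict[str, Repertoire] = {}

    # baseline PBMC: spikes absent unless deliberately leaked
    if config.leak_spikes_into_baseline and config.n_spike:
        keys0 = list(base_keys) + list(spike_keys)
        freq0 = np.concatenate(
            [base_freq * (1 - spike_total),
             np.full(config.n_spike, config.spike_freq)]
        )
    else:
        keys0, freq0 = list(base_keys), base_freq
    samples["pbmc_baseline"] = _draw(
        pbmc_meta("baseline"), keys0, freq0, config.depth, rng
    )

    # week 7: persisting baseline clones renormalized around the spikes
    mask7 = rng.random(config.n_clones) < config.persistence
    if not mask7.any():
        mask7[0] = True
    w7_base = base_freq * mask7
    w7_base = w7_base / w7_base.sum() * (1 - spike_total)
    keys7 = list(base_keys) + list(spike_keys)
    freq7_unstim = np.concatenate(
        [w7_base, np.full(config.n_spike, config.spike_freq)]
    )
    freq7_stim = np.concatenate(
        [w7_base, np.full(config.n_spike, config.spike_freq * config.spike_fold)]
    )
    samples["pbmc_week7_unstim"] = _draw(
        pbmc_meta("week7"), keys7, freq7_unstim, config.depth, rng
    )
    samples["pbmc_week7_stim"] = _draw(
        pbmc_meta("week7", Stimulation.STIMULATED),
        keys7, freq7_stim, config.depth, rng,
    )

    # week 18: a second persistence step; spikes persist in vivo
    mask18 = mask7 & (rng.random(config.n_clones) < config.persistence)
    if not mask18.any():
        mask18[np.flatnonzero(mask7)[0]] = True
    w18_base = base_freq * mask18
    w18_base = w18_base / w18_base.sum() * (1 - spike_total)
    freq18 = np.concatenate([w18_base, np.full(config.n_spike, config.spike_freq)])
    samples["pbmc_week18"] = _draw(
        pbmc_meta("week18"), keys7, freq18, config.depth, rng
    )

    # tumor biopsies: a shared subset of blood clones plus private clones
    shared_mask = rng.random(config.n_clones) < config.tumor_share
    if not shared_mask.any():
        shared_mask[0] = True
    shared_keys = [k for k, m in zip(base_keys, shared_mask) if m]
    shared_freq = base_freq[shared_mask]
    priv_freq = zipf_frequencies(n_private, config.zipf_exponent)
    t0_keys = shared_keys + list(priv_base)
    t0_freq = np.concatenate(
        [shared_freq / shared_freq.sum() * 0.5, priv_freq * 0.5]
    )
    samples["tumor_baseline"] = _draw(
        tumor_meta("baseline"), t0_keys, t0_freq, config.depth, rng
    )

    persist_mask = rng.random(len(shared_keys)) < config.persistence
    if not persist_mask.any():
        persist_mask[0] = True
    tp_shared_keys = [k for k, m in zip(shared_keys, persist_mask) if m]
    tp_shared = shared_freq[persist_mask]
    tp_keys = tp_shared_keys + list(priv_post) + list(spike_keys)
    tp_freq = np.concatenate(
        [
            tp_shared / tp_shared.sum() * (0.5 - spike_total),
            priv_freq * 0.5,
            np.full(config.n_spike, config.spike_freq),
        ]
    )
    samples["tumor_post"] = _draw(
        tumor_meta("week15"), tp_keys, tp_freq, config.depth, rng
    )

    truth = pd.DataFrame(
        {
            "cdr3_aa": list(spike_keys),
            "spike_freq": config.spike_freq,
            "true_fold": config.spike_fold,
        }
    )
    return samples, truth


def _lognormal_counts(
    mean: float, cv: float, size: int, rng: np.random.Generator
) -> tuple[float, ...]:
    if cv == 0:
        return tuple(float(mean) for _ in range(size))
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2  # E[lognormal] = mean
    return tuple(float(x) for x in rng.lognormal(mu, np.sqrt(sigma2), size))


def simulate_assays(
    config: SimConfig,
    timepoints: Sequence[str] = ("baseline", "week7"),
    replicates: int = 3,
) -> list[ProliferationAssay]:
    """Triplicate proliferation counts around the configured true SI.

    Unstimulated wells are log-normal around ``base_cpm`` with CV
    ``noise_cv``; stimulated wells around ``base_cpm * si_true`` for every
    post-baseline timepoint (baseline wells are unstimulated-level, SI ~ 1,
    emulating no pre-existing vaccine response).  With ``noise_cv = 0`` the
    estimated SI equals ``si_true`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    assays = []
    for timepoint in timepoints:
        at_baseline = timepoint.strip().lower() == "baseline"
        for peptide in PEPTIDES:
            stim_mean = config.base_cpm * (1.0 if at_baseline else config.si_true)
            assays.append(
                ProliferationAssay(
                    patient_id=config.patient_id,
                    timepoint=timepoint,
                    peptide=peptide,
                    stimulated_counts=_lognormal_counts(
                        stim_mean, config.noise_cv, replicates, rng
                    ),
                    unstimulated_counts=_lognormal_counts(
                        config.base_cpm, config.noise_cv, replicates, rng
                    ),
                )
            )
    return assays
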