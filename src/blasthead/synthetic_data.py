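"""Synthetic Friedlander-shaped gauge traces.

Generates pressure time histories with the structure the analysis
stages assume — an impulse-like positive phase, the Friedlander
negative phase, geometric peak attenuation and arrival lag with depth,
and optional seeded Gaussian noise — so that injury metrics and the
scenario pipeline are testable without running either solver.

Synthetic von Mises channels are plain scaled copies of the pressure
channel, intended for plumbing tests only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from blasthead.blast_source import FriedlanderParams, friedlander
from blasthead.gauges import GaugeTrace

__all__ = ["SyntheticTraceSpec", "gen_friedlander_trace", "gen_gauge_suite"]


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Recipe for one synthetic gauge trace.

    ``noise_sd`` is the standard deviation of additive Gaussian noise in
    Pa (0 for a noiseless trace); generation is deterministic per seed.
    """

    params: FriedlanderParams
    sample_dt: float = 1.0e-6  # s
    duration: float = 5.0e-3  # s
    noise_sd: float = 0.0  # Pa
    seed: int = 0
    vm_scale: float | None = None  # optional scaled von Mises channel

    def __post_init__(self) -> None:
        if self.sample_dt <= 0 or self.duration <= 0:
            raise ValueError("sampling interval and duration must be positive")
        if self.duration < self.params.arrival_time + 2.0 * self.params.positive_duration:
            raise ValueError("duration must cover arrival plus two positive-phase lengths")
        if self.noise_sd < 0:
            raise ValueError("noise standard deviation must be non-negative")


def gen_friedlander_trace(spec: SyntheticTraceSpec, label: str = "synthetic") -> GaugeTrace:
    """Generate one Friedlander trace (zero before arrival, seeded noise)."""
    t = np.arange(0.0, spec.duration + 0.5 * spec.sample_dt, spec.sample_dt)
    p = friedlander(t, spec.params)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        p = p + rng.normal(0.0, spec.noise_sd, size=p.size)
    vm = None if spec.vm_scale is None else np.abs(p) * spec.vm_scale
    return GaugeTrace(
        time=t,
        pressure=p,
        von_mises=vm,
        label=label,
        meta={"kind": "gauge_overpressure", "seed": spec.seed},
    )


def gen_gauge_suite(
    base: SyntheticTraceSpec,
    depths: list[float],
    attenuation_per_gauge: float,
    lag_per_gauge: float,
) -> list[GaugeTrace]:
    """Generate a proximal-to-distal gauge suite.

    Gauge ``k`` (k = 0 proximal) has peak ``dP * (1 - a)^k`` and arrival
    ``t_a + k * lag`` — the geometric-attenuation, constant-lag pattern
    of a pressure wave crossing the brain.  Each gauge gets an
    independent noise stream derived from the base seed.
    """
    if not (0.0 <= attenuation_per_gauge < 1.0):
        raise ValueError("attenuation per gauge must be in [0, 1)")
    if lag_per_gauge < 0:
        raise ValueError("lag per gauge must be non-negative")
    traces = []
    for k, depth in enumerate(depths):
        pars = FriedlanderParams(
            peak_overpressure=base.params.peak_overpressure
            * (1.0 - attenuation_per_gauge) ** k,
            arrival_time=base.params.arrival_time + k * lag_per_gauge,
            positive_duration=base.params.positive_duration,
            decay_b=base.params.decay_b,
        )
        spec_k = replace(base, params=pars, seed=base.seed + k)
        tr = gen_friedlander_trace(spec_k, label=f"depth_{depth * 1e3:.0f}mm")
        tr.meta["depth_m"] = float(depth)
        traces.append(tr)
    return traces
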