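"""Shared fixtures: small synthetic recordings and montages."""

from dataclasses import replace

import numpy as np
import pytest

from motionerp import (
    ComponentParams,
    NoiseProfile,
    PipelineConfig,
    SubjectSpec,
    default_conditions,
    generate_subject,
    load_montage,
)


@pytest.fixture(scope="session")
def montage():
    return load_montage()


def zero_noise_conditions(names=("slow", "fast")):
    """Study conditions with all trial-to-trial SDs zeroed."""
    out = []
    for c in default_conditions():
        if c.name not in names:
            continue
        cp = {
            k: ComponentParams(p.latency_mean, 0.0, p.amplitude_mean, 0.0)
            for k, p in c.component_params.items()
        }
        out.append(
            replace(
                c,
                component_params=cp,
                emg_delay=(c.emg_delay[0], 0.0),
                motor_time=(c.motor_time[0], 0.0),
            )
        )
    return out


def quiet_profile():
    return NoiseProfile(broadband_sd=0.0, blink_rate=0.0, artifact_fraction=0.0)


@pytest.fixture(scope="session")
def zero_noise_subject():
    """Noiseless, jitter-free subject: the exact-recovery fixture."""
    spec = SubjectSpec("Z01", noise_profile=quiet_profile(), seed=11)
    return generate_subject(spec, zero_noise_conditions())


@pytest.fixture(scope="session")
def small_noisy_subject():
    """One fast-condition subject with default noise, 20 trials (fast to
    process; used by bookkeeping and smoke tests)."""
    conds = [replace(c, n_trials=20) for c in default_conditions()
             if c.name == "fast"]
    spec = SubjectSpec("N01", seed=21)
    return generate_subject(spec, conds)


@pytest.fixture()
def bypass_config():
    cfg = PipelineConfig()
    cfg.csd.bypass = True
    return cfg
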