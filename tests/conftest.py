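import numpy as np
import pytest

from riskseq.maze import MazeGeometry, frame_features
from riskseq.perievent import align_events
from riskseq.photometry import preprocess_session
from riskseq.sequences import detect_sequences
from riskseq.synthetic import SimConfig, default_script, simulate_session, simulate_trajectory


@pytest.fixture()
def geometry():
    return MazeGeometry()


@pytest.fixture(scope="session")
def scripted_session():
    """One 200-s session with a 5 C->C + 3 NoGo + 2 Go script."""
    script = default_script({"C->C": 5, "NoGo": 3, "Go": 2}, t_first=15, spacing=14)
    config = SimConfig(session_duration=200.0, sequence_script=script, seed=3)
    geometry = MazeGeometry()
    track, events, truth = simulate_trajectory(config, geometry)
    features = frame_features(track, geometry)
    return {
        "config": config,
        "geometry": geometry,
        "track": track,
        "events": events,
        "truth": truth,
        "features": features,
    }


def build_cohort(
    n_animals: int,
    amplitudes: dict,
    noise_sd: float = 0.2,
    artifact_amplitude: float = 0.1,
    base_seed: int = 100,
    amp_jitter: float = 0.2,
    session_duration: float = 600.0,
    counts: dict | None = None,
):
    """Full-pipeline cohort: simulate -> preprocess -> detect -> align for
    several animals, with mild between-animal amplitude heterogeneity."""
    counts = counts or {"C->C": 5, "NoGo": 4, "Go": 4}
    script = default_script(counts, t_first=15, spacing=14)
    geometry = MazeGeometry()
    rng = np.random.default_rng(base_seed)
    units, truths = [], []
    for a in range(n_animals):
        scale = rng.uniform(1 - amp_jitter, 1 + amp_jitter)
        config = SimConfig(
            session_duration=session_duration,
            sequence_script=script,
            seed=base_seed + a,
            effect_amplitudes={k: v * scale for k, v in amplitudes.items()},
            artifact_amplitude=artifact_amplitude,
            noise_sd=noise_sd,
        )
        track, events, truth, session = simulate_session(
            config, geometry, animal=f"m{a}"
        )
        trace = preprocess_session(session)
        features = frame_features(track, geometry)
        table = detect_sequences(features, events, geometry, animal=f"m{a}")
        units.extend(align_events(trace, table))
        truths.append(truth)
    return units, truths


@pytest.fixture(scope="session")
def effect_cohort():
    """Six animals with graded per-type transients through the full
    pipeline."""
    return build_cohort(
        6, {"C->C": 0.04, "NoGo": 0.02, "Go": -0.04}, base_seed=100
    )
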