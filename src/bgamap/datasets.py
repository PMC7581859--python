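"""Ready-made synthetic study sessions.

These builders wire the protocol generator and the recording simulator into
complete sessions under the study conditions: the 650-stimulus protocol
(scenes, objects, faces 100 x 2 plus a 25 x 2 fruit/vegetable target; 300 ms
stimuli every 1,100 ms in blocks of five with 3-s pauses), event-locked
multiplicative gamma gains of 10-60% with onsets of 100-400 ms and durations
of 100-500 ms, occasional interictal spikes, and electrode positions drawn
around centroids of known scene- and object-selective areas (parahippocampal,
occipital and medial place areas; lateral occipital complex).  Scaled-down
variants (fewer unique pictures, fewer channels) keep simulation studies
cheap while preserving the statistical structure.
"""

from __future__ import annotations

import numpy as np

from .protocol import CategorySpec, ProtocolSpec, build_protocol, default_protocol
from .simulate import ChannelSpec, EffectSpec, SimulatedSession, simulate_recording

__all__ = ["small_protocol", "make_study_session", "SCENE_CENTROIDS", "OBJECT_CENTROIDS"]

# MNI centroids (|x| folded to the right) of known scene-/object-selective
# areas, used to plant geometries: PPA-, OPA- and MPA-like for scenes;
# LO- and pFs-like for objects.
SCENE_CENTROIDS = [(30.0, -45.0, -7.0), (38.0, -76.0, 24.0), (16.0, -53.0, 12.0)]
OBJECT_CENTROIDS = [(46.0, -63.0, 4.0), (37.0, -34.0, -20.0), (27.0, -63.0, 34.0)]
_NULL_CENTROID = (40.0, 10.0, 30.0)  # frontal, away from the visual areas


def small_protocol(n_unique: int = 25, n_target: int = 5, seed: int = 0) -> ProtocolSpec:
    """Scaled-down study protocol: scene/object x (n_unique x 2) + small target set."""
    return ProtocolSpec(
        categories=(
            CategorySpec("scene", n_unique, 2),
            CategorySpec("object", n_unique, 2),
            CategorySpec("fruit", n_target, 2),
        ),
        target_category="fruit",
        seed=seed,
    )


def _mk_channels(
    rng: np.random.Generator,
    n_scene: int,
    n_object: int,
    n_null: int,
    gain: float | None = None,
    onset: float | None = None,
    duration: float | None = None,
    spike_rate: float = 0.0,
    spread_mm: float = 6.0,
) -> list[ChannelSpec]:
    """Channel specs with effects drawn from the study's parameter ranges.

    When ``gain``/``onset``/``duration`` are given they are used for every
    responsive channel; otherwise each channel draws gain ~ U(0.10, 0.60),
    onset ~ U(0.10, 0.40) s and duration ~ U(0.10, 0.50) s.
    """
    specs: list[ChannelSpec] = []

    def _effect() -> EffectSpec:
        return EffectSpec(
            onset=onset if onset is not None else float(rng.uniform(0.10, 0.40)),
            duration=duration if duration is not None else float(rng.uniform(0.10, 0.50)),
            peak_gain=gain if gain is not None else float(rng.uniform(0.10, 0.60)),
        )

    def _pos(centroids) -> tuple[float, float, float]:
        c = centroids[rng.integers(len(centroids))]
        p = np.asarray(c) + rng.normal(0, spread_mm, 3)
        if rng.random() < 0.5:  # either hemisphere
            p[0] = -p[0]
        return (float(p[0]), float(p[1]), float(p[2]))

    counter = 0
    for n, cat, centroids, region in (
        (n_scene, "scene", SCENE_CENTROIDS, "phlg"),
        (n_object, "object", OBJECT_CENTROIDS, "loc"),
        (n_null, None, [_NULL_CENTROID], "fc"),
    ):
        for i in range(n):
            counter += 1
            effects = {cat: _effect()} if cat else {}
            specs.append(
                ChannelSpec(
                    name=f"ch{counter:03d}",
                    shaft=f"S{(counter - 1) // 6 + 1}",
                    mni=_pos(centroids),
                    region=region,
                    effects=effects,
                    spike_rate=spike_rate,
                )
            )
    return specs


def make_study_session(
    seed: int = 0,
    n_scene: int = 6,
    n_object: int = 6,
    n_null: int = 12,
    n_unique: int | None = 25,
    gain: float | None = None,
    onset: float | None = None,
    duration: float | None = None,
    spike_rate: float = 0.02,
    fs: float = 512.0,
) -> SimulatedSession:
    """One synthetic session under (optionally scaled-down) study conditions.

    ``n_unique=None`` uses the full 650-stimulus protocol; an integer builds
    the scaled variant with that many unique scene/object pictures (x2
    repeats each).  Effects default to the study parameter ranges.
    """
    ss = np.random.SeedSequence(seed)
    s_proto, s_chan, s_rec = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    spec = default_protocol(seed=s_proto) if n_unique is None else small_protocol(
        n_unique=n_unique, seed=s_proto
    )
    events = build_protocol(spec)
    rng = np.random.default_rng(s_chan)
    channels = _mk_channels(
        rng, n_scene, n_object, n_null,
        gain=gain, onset=onset, duration=duration, spike_rate=spike_rate,
    )
    return simulate_recording(events, channels, fs=fs, seed=s_rec)
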