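import numpy as np
import pytest

import hcrprof as hp


def profiles_from_scene(scene):
    """Render a scene and run it through projection, extraction and normalization."""
    stacks, truth = hp.generate_scene(scene)
    profiles = [
        hp.normalize_profile(hp.extract_profile(hp.max_project(stack), line))
        for stack, line in zip(stacks, truth.lines)
    ]
    return profiles, truth


def gaussian_average(
    grid, centers, widths, amplitudes, baseline=0.0, label="q", ref=None, n=5
):
    """Analytic AverageProfile with zero s.e.m., optionally with a reference channel.

    ``ref`` is an optional (center, width, amplitude) triple for a second
    channel named 'ref'.
    """
    grid = np.asarray(grid, dtype=float)

    def curve(cs, ws, amps):
        out = np.full(grid.shape, float(baseline))
        for c, w, a in zip(cs, ws, amps):
            out += a * np.exp(-((grid - c) ** 2) / (2.0 * w**2))
        return out

    means = [curve(centers, widths, amplitudes)]
    labels = [label]
    if ref is not None:
        c, w, a = ref
        means.insert(0, curve([c], [w], [a]))
        labels.insert(0, "ref")
    means = np.vstack(means)
    return hp.AverageProfile(
        grid=grid,
        means=means,
        sems=np.zeros_like(means),
        n=n,
        channel_labels=tuple(labels),
    )


@pytest.fixture(scope="session")
def stage13_average():
    profiles, _ = profiles_from_scene(hp.stage13_scene(seed=11))
    return hp.average_profiles(hp.align_profiles(profiles, "pax3"))


@pytest.fixture(scope="session")
def stage17_average():
    profiles, _ = profiles_from_scene(hp.stage17_scene(seed=11))
    return hp.average_profiles(hp.align_profiles(profiles, "snai2"))
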