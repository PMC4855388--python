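"""Shared fixtures: small synthetic morph collections, built once per session."""

import numpy as np
import pandas as pd
import pytest

from mimiscape import cpm, synthetic_data as sd


@pytest.fixture(scope="session")
def band_parents():
    """Two morphs differing only in the vertical position of a yellow band."""
    hom1 = sd.MorphSpec(
        name="p1",
        pattern_elements=[sd.PatchSpec("ellipse", (0.5, 0.38), (0.28, 0.08), "yellow")],
    )
    hom2 = sd.MorphSpec(
        name="p2",
        pattern_elements=[sd.PatchSpec("ellipse", (0.5, 0.60), (0.28, 0.08), "yellow")],
    )
    return hom1, hom2


@pytest.fixture(scope="session")
def small_colormaps(band_parents):
    """Six noiseless colour maps: parents, two blends and two exotics."""
    hom1, hom2 = band_parents
    exotic1 = sd.MorphSpec(
        name="x1",
        pattern_elements=[sd.PatchSpec("ellipse", (0.40, 0.5), (0.10, 0.10), "white")],
    )
    exotic2 = sd.MorphSpec(
        name="x2",
        pattern_elements=[sd.PatchSpec("ellipse", (0.62, 0.5), (0.10, 0.10), "orange")],
    )
    images = [
        sd.render_morph(hom1, (48, 48)),
        sd.render_morph(hom2, (48, 48)),
        sd.blend_heterozygote(sd.DominanceBlend(hom1, hom2, 0.7), (48, 48), name="b07"),
        sd.blend_heterozygote(sd.DominanceBlend(hom1, hom2, 0.4), (48, 48), name="b04"),
        sd.render_morph(exotic1, (48, 48)),
        sd.render_morph(exotic2, (48, 48)),
    ]
    return [cpm.categorize_pixels(img) for img in images]


@pytest.fixture(scope="session")
def fitted_template(small_colormaps):
    template, transforms = cpm.build_average_template(small_colormaps)
    return template, transforms


@pytest.fixture(scope="session")
def aligned_set(small_colormaps, fitted_template):
    template, _ = fitted_template
    return {c.specimen_id: cpm.align_to_template(c, template)
            for c in small_colormaps}


@pytest.fixture(scope="session")
def binary_pca(aligned_set):
    ids = sorted(aligned_set)
    feats = pd.DataFrame(
        np.stack([cpm.binary_encode(aligned_set[i]) for i in ids]), index=ids)
    return cpm.fit_pattern_pca(feats, n_components=8, encoding="binary")


def make_predation_table(counts_per_role: dict, n_per_group: int = 100,
                         site_group: str = "g1") -> pd.DataFrame:
    """Build a PredationTable with exact per-role attack counts (one group)."""
    frames = []
    for role, n_attacked in counts_per_role.items():
        attacked = np.zeros(n_per_group, dtype=bool)
        attacked[:n_attacked] = True
        frames.append(pd.DataFrame({
            "site": "s1",
            "site_group": site_group,
            "group": np.arange(n_per_group),
            "role": role,
            "recovered": True,
            "attacked": pd.array(attacked, dtype="boolean"),
        }))
    return pd.concat(frames, ignore_index=True)
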