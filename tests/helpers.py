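"""Shared synthetic feature-row generator for the clustering tests."""

import numpy as np

from bctseg.vessel_cls import (
    ComponentFeatures,
    ROLE_CIRCULAR,
    ROLE_FIBRO,
    ROLE_TUBULAR,
)


def table1_features(rng, n=60):
    """Synthetic rows following the qualitative class profiles:

    circular  : high C, high AR, few inflections, low variance
    tubular   : low C, low AR, some inflections, low variance
    irregular : mid C/AR, many inflections, high variance
    """
    rows, labels = [], []
    profiles = {
        ROLE_CIRCULAR: dict(var=(3e-4, 1e-4), c=(0.95, 0.05), ar=(0.85, 0.05), infl=(0.5, 0.5)),
        ROLE_TUBULAR: dict(var=(3e-4, 1e-4), c=(0.4, 0.07), ar=(0.2, 0.05), infl=(2.0, 1.0)),
        ROLE_FIBRO: dict(var=(1.2e-3, 2e-4), c=(0.55, 0.1), ar=(0.5, 0.1), infl=(10.0, 2.5)),
    }
    for role, p in profiles.items():
        for _ in range(n):
            rows.append(
                ComponentFeatures(
                    slice_index=0,
                    component_id=len(rows) + 1,
                    variance=max(rng.normal(*p["var"]), 1e-6),
                    circularity=max(rng.normal(*p["c"]), 0.05),
                    aspect_ratio=float(np.clip(rng.normal(*p["ar"]), 0.02, 1.0)),
                    n_inflections=max(int(round(rng.normal(*p["infl"]))), 0),
                )
            )
            labels.append(role)
    return rows, labels
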