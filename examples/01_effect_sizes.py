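"""Effect sizes for a handful of paired cover-crop comparisons.

Builds three paired comparisons by hand, computes the ln response ratio,
its nonparametric variance, and the back-transformed percentage change.
"""

from ccmeta import (
    Observation,
    ObservationSet,
    Response,
    compute_effects,
    percent_change,
)

obs = ObservationSet.from_observations(
    [
        # cover crop leached 31 kg N/ha vs 100 under fallow, 4 reps each
        Observation("smith2019", "o1", Response.NITRATE_LEACHING, 31.0, 100.0, 4, 4),
        # unreplicated report: n defaults to 1 on ingestion, here explicit
        Observation("li2020", "o2", Response.NITRATE_LEACHING, 18.0, 24.0, 1, 1),
        # no effect: identical means
        Observation("okoro2021", "o3", Response.NITRATE_LEACHING, 40.0, 40.0, 3, 4),
    ]
)

effects = compute_effects(obs)
for _, r in effects.iterrows():
    print(
        f"{r.obs_id}: ln R = {r.es:+.4f}, v = {r.v:.4f}, "
        f"%change = {percent_change(r.es):+.1f}%"
    )

# ln R < 0 means the cover crop reduced leaching; v depends only on the
# replicate counts (2.0 for an unreplicated pair), so sparse reports get
# the least weight.
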