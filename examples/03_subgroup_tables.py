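"""Moderator (subgroup) analysis: Q-partition across cover-crop families.

Runs the full analysis on a synthetic leaching table and prints the
family table with its within/between heterogeneity partition.
"""

from ccmeta import default_config, generate, run_analysis

obs = generate(default_config("nitrate_leaching"), seed=1)
run = run_analysis(obs, moderators=["cc_family", "tillage"])

tab = run.tables["cc_family"]
print(tab.rows[["level", "n", "Q", "df", "p_hetero", "I2", "pct_change"]]
      .to_string(index=False, float_format=lambda x: f"{x:.1f}"))
qw, dfw, pw = tab.total_within
qb, dfb, pb = tab.total_between
print(f"Total within : Q = {qw:.0f}, df = {dfw}, p = {pw:.3f}")
print(f"Total between: Q = {qb:.0f}, df = {dfb}, p = {pb:.3f}")
print(f"Overall      : Q = {tab.overall_het.Q:.0f}, df = {tab.overall_het.df}")

# Q_within + Q_between = Q_overall exactly (fixed-effect weights); a
# significant between-Q says family membership explains real differences
# in cover-crop efficacy. Generating truth: Brassicaceae -75%, Poaceae
# and mixtures -52%, legumes -40%, Asteraceae 0%.
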