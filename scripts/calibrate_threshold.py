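"""Recompute the shipped mining thresholds from the curated precursor tables.

The default threshold is (minimum best-parse log-odds over the curated
nonrepetitive precursors) - 1 nat, so every curated precursor passes with
margin; the leader-only threshold used for pseudogene candidates is
calibrated the same way on leader scores. Run from the repository root:

    python scripts/calibrate_threshold.py
"""

from msdin import calibrate_thresholds, dedup_genes, load_packaged_fixtures

full, leader = calibrate_thresholds(dedup_genes(load_packaged_fixtures()))
print(f"DEFAULT_THRESHOLD = {full:.2f}")
print(f"DEFAULT_LEADER_THRESHOLD = {leader:.2f}")
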