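"""Metaphase index and mitotic-timing summaries from annotated tables.

These statistics take hand-annotated inputs (event times from time-lapse
movies, metaphase counts from population snapshots), not images: the
package computes the summaries, it does not detect the events.
"""

from kinetoquant import MetaphaseCounts, TimingRecord, metaphase_index, timing_summary

counts = [
    MetaphaseCounts("rep1", "control", 21, 512),
    MetaphaseCounts("rep2", "control", 25, 498),
    MetaphaseCounts("rep3", "control", 19, 505),
    MetaphaseCounts("rep1", "LIC2", 86, 490),
    MetaphaseCounts("rep2", "LIC2", 95, 520),
    MetaphaseCounts("rep3", "LIC2", 78, 475),
]
print(metaphase_index(counts).to_string(index=False))
print("\nMetaphase index = % of living cells in metaphase, mean +/- SD over replicates.\n")

records = [
    TimingRecord("c1", "control", 0, 400, t_anaphase_min=28),
    TimingRecord("c2", "control", 0, 400, t_anaphase_min=35),
    TimingRecord("c3", "control", 0, 400, t_anaphase_min=41),
    TimingRecord("c4", "LIC2", 0, 400, t_anaphase_min=30),
    TimingRecord("c5", "LIC2", 0, 400, t_anaphase_min=40),
    TimingRecord("c6", "LIC2", 0, 400, t_anaphase_min=90),
    TimingRecord("c7", "LIC2", 0, 400, t_death_min=260),
    TimingRecord("c8", "LIC2", 0, 720),  # still arrested at movie end
]
summary = timing_summary(records, arrest_threshold_min=80, death_window_min=240)
print(summary.to_string(index=False))
print(
    "\nA cell counts as arrested if it has not entered anaphase within 80 min "
    "of nuclear envelope breakdown; among arrested cells the death fraction "
    "counts deaths later than 4 h after NEB."
)
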