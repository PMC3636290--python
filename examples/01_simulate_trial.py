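"""Simulate the full two-arm consensus trial and inspect its artefacts.

Eight game-based (HC) groups and seven face-to-face (IC) groups of eight
participants answer four low-back-pain scenarios at three rounds.
"""

from consensim import default_behavior, default_design, simulate_trial, validate_trial

trial = simulate_trial(default_design(), default_behavior(), seed=1)

print(f"answer records : {len(trial.table.frame)}")   # 120 participants × 4 × 3
print(f"HC transcripts : {len(trial.transcripts)}")   # 8 groups × 4 teams × 4 scenarios
print(f"validation     : {validate_trial(trial.table)}")

gid, ranking = next(iter(trial.rankings.items()))
print(f"\ngame ranking of group {gid} (consensus count, limit violations, total s):")
for place, e in enumerate(ranking, 1):
    print(f"  {place}. {e.team_id}: {e.consensus_count} consensus, "
          f"{e.exceed_count} over limit, {e.total_time:.0f} s")
# Teams reaching consensus on more scenarios, faster and within the time
# limit, rank higher; the ranking is the game's competition element only.
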