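#!/usr/bin/env python
"""Generate a desk-scale synthetic cohort on disk and describe it.

Writes EDF recordings, event files, a behavior table and a manifest to
results/cohort/.  The cohort emulates the Go/No-go VR classroom task: per
block 100 target + 50 non-target stimuli at 1500 ms onset spacing (here a
reduced block for desk-scale runtimes), two conditions per participant
(N-D: no distractor, Y-D: visual distractor).
"""

import argparse
from pathlib import Path

from vrcpt import synth

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

cfg = synth.default_config(seed=args.seed, n_participants=4,
                           sampling_rate=250.0, n_target=20, n_nontarget=10)
manifest = synth.generate_cohort(cfg, args.out)

ev = synth.cohort_events(cfg, 0, "N-D")
print(f"cohort written to {args.out} (config hash {manifest['config_hash']})")
print(f"  participants: {cfg.n_participants}, conditions: N-D / Y-D")
print(f"  channels ({len(cfg.channels)}): {', '.join(cfg.channels)}")
print(f"  events per block: {ev.n_target} target + {ev.n_nontarget} non-target, "
      f"onset spacing {ev.stim_ms + ev.isi_ms:.0f} ms")
print(f"  recordings: {len(manifest['recordings'])} EDF files "
      f"at {cfg.sampling_rate:.0f} Hz")
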