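"""Simulate the pSHG acquisition campaign: 4 samples x (6 NM + 4 EM + 4 LM).

Each acquisition is a 512 x 512 x 12 stack (polarization rotated 0-165 deg
in 15-degree steps) generated from the region's ground-truth organization
parameter I2 with shot noise at a0 = 500 counts.  Stacks are binary and go
under scratch/.
"""

import argparse
import json
import time
from pathlib import Path

import numpy as np

from colhier import io, presets, synthetic


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--shape", type=int, default=512)
    ap.add_argument("--samples", type=int, default=presets.PSHG_N_SAMPLES)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", default="scratch/pshg")
    args = ap.parse_args()

    t0 = time.time()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    ss = np.random.SeedSequence(args.seed)
    n_total = args.samples * sum(presets.PSHG_ACQUISITIONS_PER_SAMPLE.values())
    children = ss.spawn(n_total)
    i = 0
    for sample in range(1, args.samples + 1):
        for region in presets.REGIONS:
            for k in range(presets.PSHG_ACQUISITIONS_PER_SAMPLE[region]):
                seed_i = int(children[i].generate_state(1)[0] % (2**31))
                scene = presets.pshg_scene_for_region(
                    region, shape=(args.shape, args.shape), seed=seed_i
                )
                stack, angles = synthetic.generate_pshg_stack(scene)
                name = f"TLT{sample}_{region}_{k}.tif"
                io.write_pshg_stack(
                    out / name, stack, angles, seed=seed_i,
                    ground_truth={"region": region,
                                  "i2": presets.PSHG_REGION_I2[region]},
                )
                index.append(dict(stack=name, sample=sample, region=region))
                i += 1
    (out / "index.json").write_text(json.dumps(index, indent=2))
    io.write_manifest(
        out / "manifest.json", "analysis/03_simulate_pshg", seed=args.seed,
        config=vars(args), counts={"acquisitions": len(index)},
    )
    print(f"simulated {len(index)} pSHG acquisitions "
          f"({args.shape}x{args.shape}x12) in {time.time() - t0:.1f}s -> {out}")


if __name__ == "__main__":
    main()
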