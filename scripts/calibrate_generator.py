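#!/usr/bin/env python
"""One-off calibration sweep for the simulated-benchmark generator.

Evaluates candidate generator settings (graph density, module degree
band, disruption depth, removal targeting) by the benchmark metrics the
extraction criterion achieves on them.  The chosen values are frozen as
the ``SimulationConfig`` defaults; rerun this only when the generator
design itself changes.

Usage:
    python scripts/calibrate_generator.py [n_pairs] [master_seed]
"""

from __future__ import annotations

import itertools
import sys
import time

from ckds.evaluate import benchmark, summarize_benchmark
from ckds.simulate import SimulationConfig, generate_dataset


def probe(n_pairs: int, master_seed: int, **overrides) -> None:
    config = SimulationConfig(**overrides)
    t0 = time.time()
    dataset = generate_dataset(config, n_pairs, master_seed)
    table = benchmark(dataset, algorithms=("ckds",))
    s = summarize_benchmark(table).loc["ckds"]
    n_err = int((table["error"] != "").sum())
    print(
        f"{overrides or 'defaults'}: "
        f"acc {s.accuracy * 100:.2f}% prec {s.precision:.3f} "
        f"rec {s.recall * 100:.1f}% f1 {s.f1:.3f} "
        f"(kds size {table.n_kds.mean():.1f}, {n_err} failures, "
        f"{time.time() - t0:.0f}s)",
        flush=True,
    )


def main() -> None:
    n_pairs = int(sys.argv[1]) if len(sys.argv) > 1 else 30
    seed = int(sys.argv[2]) if len(sys.argv) > 2 else 11
    probe(n_pairs, seed)  # frozen defaults first
    for attachment, disruption in itertools.product((5, 6, 7), (0.5, 0.7)):
        probe(n_pairs, seed, attachment=attachment, disruption_rate=disruption)


if __name__ == "__main__":
    main()
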