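# Benchmark chemostat run: single-peak landscape, tenth-scale duration.
# Usage: coevostat simulate --config examples/benchmark.yaml --seed 0 --out out/
parameters:
  T: 2.0e6        # min; the full-length design runs 2.0e7
landscape:
  kind: single_peak
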