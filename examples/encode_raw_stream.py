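"""Encode a raw acceleration stream into 8-bit 5-min activity values.

Builds one synthetic 10-min stream (quiet first half, vigorous second half)
and runs the on-collar Activity Mode 1 computation: down-sampling, mean
absolute first differences, and quantization to the 0-255 scale.
"""

import numpy as np
import pandas as pd

from collarbehavior import RawAccelStream, encode_activity_mode1, first_diff_to_activity

rng = np.random.default_rng(0)
rate = 128  # Hz, Vertex Plus
t = np.arange(10 * 60 * rate) / rate

# gravity on Z, plus a gait oscillation that grows in the second 5 minutes
amplitude = np.where(t < 300, 0.02, 0.40)  # g
signal = amplitude * np.sin(2 * np.pi * 2.0 * t)
samples = np.column_stack([signal, 0.5 * signal, 1.0 + signal])
samples += rng.normal(0, 0.01, size=samples.shape)

stream = RawAccelStream(
    animal_id="demo", t0=pd.Timestamp("2022-06-01"), rate=rate,
    samples=samples, unit="g",
)
for rec in encode_activity_mode1(stream):
    print(f"{rec.interval_start}  X={rec.act_x:3d}  Y={rec.act_y:3d}  Z={rec.act_z:3d}")

# the elementwise converter, for users who already averaged first differences
print("0.016 g of mean |first diff| ->", first_diff_to_activity([0.016], "g")[0])
print(
    "Each row is one 5-min interval; larger values mean more movement. The "
    "quiet interval encodes near zero, the vigorous one far higher."
)
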