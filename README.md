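# glovecal

Neural-network calibration and joint-angle computation for bend-sensor
data gloves.

Data gloves place a flexible sensor over each finger joint and report a
12-bit integer (0–4095) per sensor. Turning those integers into joint
angles normally requires a calibration routine — flat hand, full fist —
and a linear interpolation between the two captured extremes. That
fails people who cannot make a fist (arthritis, stroke, Parkinson's),
and it is biased whenever the sensor's response is nonlinear or the
glove fits poorly. `glovecal` implements the alternative: a small
back-propagation network per sensor, trained once per glove hand size
on a handful of (raw reading, reference angle) sample points, generates
a complete lookup table mapping every achievable raw value to an angle.
At runtime the wearer only holds their hand flat for a moment; each
reading is then converted by

```
key   = clip(raw − flat_hand_raw, 0, len(table) − 1)
angle = table[key]
```

The package is aimed at rehabilitation-technology and movement-science
researchers who want to reproduce, stress-test or extend this
calibration scheme without glove hardware: it bundles a synthetic
10-sensor glove simulator, the from-scratch network trainer, the
table builder, the traditional linear baseline, and the
repeatability/accuracy statistics used to compare the two methods.

## The model

For each sensor a 1–7–2 fully connected network (sigmoid activations,
biases, one output echoing the normalized raw input, one carrying the
angle) is trained by batch gradient descent with momentum,

    Δw(t) = −η ∂E/∂w + α Δw(t−1),   η = α = 0.1,

on 13 sample points for MCP sensors (0–95°) and 14 for PIP sensors
(0–105°), for 100,000 epochs; the weights of the lowest-MSE epoch are
kept. The trained net is evaluated at every raw value from the
flat-hand reading to 4095 (the *solution array*), entries beyond the
joint's physical limit are discarded, and the result is re-keyed by
`raw − flat_hand_raw`. The linear baseline is
`theta_max · clip((raw − raw_min)/(raw_max − raw_min), 0, 1)`.
See `docs/methods.md` for normalization details, the simulator's error
model, and the evaluation statistics (range/SD repeatability, Pearson
R², Bland–Altman limits of agreement, t-based CIs).

## Worked example

Calibrate a simulated nonlinear index-MCP sensor and read an angle:

```python
import glovecal as gc
from glovecal.bpnn import NetworkConfig

truth = gc.SensorGroundTruth(sensor_id="index_mcp", r_flat=1201,
                             gain=1500, curvature=3.0)
model = gc.SensorCalibration.from_simulation(
    truth, gc.HandFitProfile.neutral(), config=NetworkConfig(seed=0))
res = model.fit()
print(res.summary())
print("angle at raw 1257:", round(res.predict(1257)[0], 2), "deg")
```

```
Sensor calibration (back-propagation network)
====================================================
sensor:            index_mcp
hand size:         7.75 in
training samples:  13
joint limit:       95 deg
flat-hand raw:     1201
table length:      1538
best epoch:        99999
best MSE:          9.635e-05
max |residual|:    4.17 deg
table monotone:    True
----------------------------------------------------
  raw    target(deg)  fitted(deg)  resid(deg)
   1201         0.0         0.00       0.00
   1474         5.0         5.57       0.57
   ...
   2658        85.0        84.92      -0.08
   2701        95.0        90.83      -4.17

angle at raw 1257: 0.35 deg
```

The summary shows the 13 calibration sample points, the size of the
generated table (1538 raw values from the flat-hand reading 1201), and
the fit quality: sub-degree to ~2° at interior angles, worst at the
very top of the grid where the table is truncated at the 95° joint
limit anyway. A reading of 1257 is 56 counts above the flat-hand value,
so it indexes table entry 56 — here 0.35°, a barely flexed joint.

The same workflow is available from the shell:

```bash
glovecal train --sensor index_mcp --curvature 3 --seed 0 --out net.json
glovecal calibrate --net net.json --flat-hand-raw 1201 --out table.json
glovecal simulate --protocol D --curvature 3 --out rec.csv
glovecal evaluate --seeds 20 --out report.json
glovecal run-all --out-dir artifacts/
```

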