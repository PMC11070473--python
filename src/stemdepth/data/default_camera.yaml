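color:
  fx: 615.0
  fy: 615.0
  cx: 424.0
  cy: 240.0
  width: 848
  height: 480
depth:
  fx: 425.0
  fy: 425.0
  cx: 424.0
  cy: 240.0
  width: 848
  height: 480
depth_to_color:
  R:
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  t:
  - 0.0148
  - 0.0
  - 0.0
depth_scale: 0.001
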