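# Published / bench-measured characteristics of magnetic pulsers used in
# bird orientation experiments.  Fields in mT, rise times in seconds.
devices:
  - name: sota_double_wrapped
    b_peak_treat: 100.0          # slightly over 0.1 T
    rise_fraction: 0.5           # 50% of peak ...
    rise_time: 1.0e-4            # ... within 0.1 ms
    b_peak_control: 1.0          # leak pulse in antiparallel mode
    control_mode: scaled_leak
    notes: double-wrapped solenoid; antiparallel control leaks a scaled pulse
  - name: indoor_0p5t
    b_peak_treat: 500.0          # 0.5 T peak, ~4 ms pulse
    rise_fraction: 0.5           # assumed half peak ...
    rise_time: 5.0e-4            # ... within 0.5 ms
    b_peak_control: 0.0
    control_mode: none
    notes: indoor cage pulser; pulse shape unpublished, rise assumed
  - name: mp09_2020
    b_peak_treat: 52.0           # measured at the bird position
    rise_fraction: 0.5
    rise_time: 8.67e-4           # consistent with 30 mT/ms onset
    b_peak_control: 5.2
    control_mode: truncated_sham
    notes: modified commercial pulser, chopped shut-off, truncated sham
  - name: custom_2021
    b_peak_treat: 52.0
    rise_fraction: 0.5
    rise_time: 8.67e-4
    b_peak_control: 5.2
    control_mode: truncated_sham
    notes: custom MOSFET/flyback circuit driving the same coil
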