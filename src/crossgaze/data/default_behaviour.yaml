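version: 1
dual_severe_failure: true
groups:
  control:
    red_car_miss_p: 0.02
    tasks:
      safe_crossing:
        macrosaccade_rate: 4.1744
        macrosaccade_amplitude_median: 14.739
        microsaccade_rate: 2.4396
        microsaccade_amplitude_median: 0.93
        head_turn_rate: 0.4125
        head_turn_amplitude_median: 25.0
        crossing_delay_median: 1.8
        crossing_delay_median_w2: 1.79
      car_counting:
        macrosaccade_rate: 3.6144
        macrosaccade_amplitude_median: 15.023
        microsaccade_rate: 2.9459
        microsaccade_amplitude_median: 0.9399
        head_turn_rate: 0.7718
        head_turn_amplitude_median: 25.0
        crossing_delay_median: 1.8
        crossing_delay_median_w2: 1.79
  central:
    red_car_miss_p: 0.05
    tasks:
      safe_crossing:
        macrosaccade_rate: 4.8233
        macrosaccade_amplitude_median: 12.232
        microsaccade_rate: 2.5033
        microsaccade_amplitude_median: 0.9725
        head_turn_rate: 0.3627
        head_turn_amplitude_median: 25.0
        crossing_delay_median: 3.11
        crossing_delay_median_w2: 3.2
      car_counting:
        macrosaccade_rate: 3.4846
        macrosaccade_amplitude_median: 14.557
        microsaccade_rate: 2.1899
        microsaccade_amplitude_median: 0.9986
        head_turn_rate: 0.623
        head_turn_amplitude_median: 25.0
        crossing_delay_median: 3.11
        crossing_delay_median_w2: 3.2
  peripheral:
    red_car_miss_p: 0.05
    tasks:
      safe_crossing:
        macrosaccade_rate: 4.2578
        macrosaccade_amplitude_median: 14.51
        microsaccade_rate: 2.4143
        microsaccade_amplitude_median: 0.946
        head_turn_rate: 0.4588
        head_turn_amplitude_median: 25.0
        crossing_delay_median: 2.68
        crossing_delay_median_w2: 3.3
      car_counting:
        macrosaccade_rate: 3.7431
        macrosaccade_amplitude_median: 15.7
        microsaccade_rate: 2.7679
        microsaccade_amplitude_median: 0.9592
        head_turn_rate: 0.7478
        head_turn_amplitude_median: 25.0
        crossing_delay_median: 2.68
        crossing_delay_median_w2: 3.3
  combined:
    red_car_miss_p: 0.1
    tasks:
      safe_crossing:
        macrosaccade_rate: 3.8693
        macrosaccade_amplitude_median: 12.064
        microsaccade_rate: 2.1663
        microsaccade_amplitude_median: 1.0621
        head_turn_rate: 0.2902
        head_turn_amplitude_median: 25.0
        crossing_delay_median: 3.09
        crossing_delay_median_w2: 3.5
      car_counting:
        macrosaccade_rate: 3.3664
        macrosaccade_amplitude_median: 15.39
        microsaccade_rate: 1.7835
        microsaccade_amplitude_median: 1.0734
        head_turn_rate: 0.4455
        head_turn_amplitude_median: 25.0
        crossing_delay_median: 3.09
        crossing_delay_median_w2: 3.5
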