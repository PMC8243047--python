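# NEWS2 (2017), SpO2 Scale 1. Half-open bands [lower, upper); integer vitals,
# temperature at one-decimal precision. Maximum attainable total: 20.
version: news2_scale1
oxygen_weight: 2
consciousness:
  alert: 0
  new_confusion: 3
  voice: 3
  pain: 3
  unresponsive: 3
parameters:
  respiratory_rate:
    - {lower: 0, upper: 9, score: 3}      # <= 8
    - {lower: 9, upper: 12, score: 1}     # 9 - 11
    - {lower: 12, upper: 21, score: 0}    # 12 - 20
    - {lower: 21, upper: 25, score: 2}    # 21 - 24
    - {lower: 25, upper: .inf, score: 3}  # >= 25
  spo2:
    - {lower: 0, upper: 92, score: 3}     # <= 91
    - {lower: 92, upper: 94, score: 2}    # 92 - 93
    - {lower: 94, upper: 96, score: 1}    # 94 - 95
    - {lower: 96, upper: 101, score: 0}   # >= 96
  systolic_bp:
    - {lower: 0, upper: 91, score: 3}     # <= 90
    - {lower: 91, upper: 101, score: 2}   # 91 - 100
    - {lower: 101, upper: 111, score: 1}  # 101 - 110
    - {lower: 111, upper: 220, score: 0}  # 111 - 219
    - {lower: 220, upper: .inf, score: 3} # >= 220
  heart_rate:
    - {lower: 0, upper: 41, score: 3}     # <= 40
    - {lower: 41, upper: 51, score: 1}    # 41 - 50
    - {lower: 51, upper: 91, score: 0}    # 51 - 90
    - {lower: 91, upper: 111, score: 1}   # 91 - 110
    - {lower: 111, upper: 131, score: 2}  # 111 - 130
    - {lower: 131, upper: .inf, score: 3} # >= 131
  temperature:
    - {lower: 0, upper: 35.1, score: 3}    # <= 35.0
    - {lower: 35.1, upper: 36.1, score: 1} # 35.1 - 36.0
    - {lower: 36.1, upper: 38.1, score: 0} # 36.1 - 38.0
    - {lower: 38.1, upper: 39.1, score: 1} # 38.1 - 39.0
    - {lower: 39.1, upper: .inf, score: 2} # >= 39.1
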