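# NEWS (2012). The physiological bands coincide with NEWS2 SpO2 Scale 1; the
# 2017 revision changed the consciousness scale (ACVPU) and added an SpO2
# scale for hypercapnic respiratory failure, not the numeric thresholds used
# here. New-onset confusion is scored as not-alert (3), consistent with how
# AVPU was applied in practice. Maximum attainable total: 20.
version: news_2012
oxygen_weight: 2
consciousness:
  alert: 0
  new_confusion: 3
  voice: 3
  pain: 3
  unresponsive: 3
parameters:
  respiratory_rate:
    - {lower: 0, upper: 9, score: 3}
    - {lower: 9, upper: 12, score: 1}
    - {lower: 12, upper: 21, score: 0}
    - {lower: 21, upper: 25, score: 2}
    - {lower: 25, upper: .inf, score: 3}
  spo2:
    - {lower: 0, upper: 92, score: 3}
    - {lower: 92, upper: 94, score: 2}
    - {lower: 94, upper: 96, score: 1}
    - {lower: 96, upper: 101, score: 0}
  systolic_bp:
    - {lower: 0, upper: 91, score: 3}
    - {lower: 91, upper: 101, score: 2}
    - {lower: 101, upper: 111, score: 1}
    - {lower: 111, upper: 220, score: 0}
    - {lower: 220, upper: .inf, score: 3}
  heart_rate:
    - {lower: 0, upper: 41, score: 3}
    - {lower: 41, upper: 51, score: 1}
    - {lower: 51, upper: 91, score: 0}
    - {lower: 91, upper: 111, score: 1}
    - {lower: 111, upper: 131, score: 2}
    - {lower: 131, upper: .inf, score: 3}
  temperature:
    - {lower: 0, upper: 35.1, score: 3}
    - {lower: 35.1, upper: 36.1, score: 1}
    - {lower: 36.1, upper: 38.1, score: 0}
    - {lower: 38.1, upper: 39.1, score: 1}
    - {lower: 39.1, upper: .inf, score: 2}
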