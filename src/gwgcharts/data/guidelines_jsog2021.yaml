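# Recommended total gestational weight gain at 40 weeks, kg, by
# pre-pregnancy BMI category (JSOG, revised March 2021).
# Each entry is [lower, upper]; a null lower bound means the
# recommendation is one-sided ("at most upper").
# Edit or copy this file to swap in other guideline sets (pre-2021 JSOG,
# IOM, ...) via `gwgcharts band --guideline <file>`.
underweight: [12.0, 15.0]
normal: [10.0, 13.0]
overweight: [7.0, 10.0]
obese: [null, 5.0]
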