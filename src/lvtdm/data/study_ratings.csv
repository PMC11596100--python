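patient_id,observer_1,observer_2,contrast
patient_01,positive,positive,positive
patient_02,positive,positive,positive
patient_03,positive,positive,positive
patient_04,positive,positive,positive
patient_05,positive,positive,positive
patient_06,positive,positive,positive
patient_07,positive,positive,positive
patient_08,positive,positive,positive
patient_09,positive,positive,positive
patient_10,positive,positive,positive
patient_11,positive,positive,positive
patient_12,positive,positive,negative
patient_13,positive,negative,negative
patient_14,positive,negative,negative
patient_15,negative,positive,negative
patient_16,negative,positive,negative
patient_17,negative,positive,negative
patient_18,negative,negative,negative
patient_19,negative,negative,negative
patient_20,negative,negative,negative
patient_21,negative,negative,negative
patient_22,negative,negative,negative
patient_23,negative,negative,negative
patient_24,negative,negative,negative
patient_25,negative,negative,negative
patient_26,negative,negative,negative
patient_27,negative,negative,negative
patient_28,negative,negative,negative
patient_29,negative,negative,negative
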