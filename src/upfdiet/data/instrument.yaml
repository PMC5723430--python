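# Default month-recall FFQ instrument.  Frequency values are times per
# month: "never" is 0; bounded ranges use the arithmetic mean of their
# endpoints; open-ended top categories are coded at their stated bound
# (2+/day -> 2/day, 6+/day -> 6/day).  Weekly ranges are converted with
# 30.4/7 weeks per month.  All values are overridable by editing this file.
food_frequency_options:
- {label: never, value: 0}
- {label: 1 time per month, value: 1.0}
- {label: 2-3 times per month, value: 2.5}
- {label: 1-2 times per week, value: 6.51}
- {label: 3-4 times per week, value: 15.2}
- {label: 5-6 times per week, value: 23.89}
- {label: 1 time per day, value: 30.4}
- {label: 2 or more times per day, value: 60.8}
beverage_frequency_options:
- {label: never, value: 0}
- {label: 1 time per month, value: 1.0}
- {label: 2-3 times per month, value: 2.5}
- {label: 1-2 times per week, value: 6.51}
- {label: 3-4 times per week, value: 15.2}
- {label: 5-6 times per week, value: 23.89}
- {label: 1 time per day, value: 30.4}
- {label: 2-3 times per day, value: 76.0}
- {label: 4-5 times per day, value: 136.8}
- {label: 6 or more times per day, value: 182.4}
condiment_fraction_options:
- {label: almost never or never, value: 0.0}
- {label: about 1/4 of the time, value: 0.25}
- {label: about 1/2 of the time, value: 0.5}
- {label: about 3/4 of the time, value: 0.75}
- {label: almost always or always, value: 1.0}
days_per_month: 30.4
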