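group,time_h,conductivity
control,4,8.31
control,8,10.40
control,12,11.63
control,24,10.90
water,4,8.48
water,8,10.64
water,12,12.30
water,24,11.87
ultrasonic,4,8.33
ultrasonic,8,10.80
ultrasonic,12,12.78
ultrasonic,24,12.81
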