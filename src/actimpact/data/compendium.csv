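kind,key,met
activity,walking,3.5
activity,running,9.8
activity,cycling,6.8
activity,soccer,7.0
activity,gym_workout,5.5
activity,swimming,6.0
domain,recreation,4.0
domain,occupation,3.5
domain,commuting,4.0
domain,household,3.0
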