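pattern,count,partition
"(0,0,0,0,0)",302,1
"(1,0,0,0,0)",7,2
"(2,0,0,0,0)",1,2
"(3,0,0,0,0)",1,1
"(0,1,0,0,0)",37,2
"(1,1,0,0,0)",5,2
"(0,2,0,0,0)",7,2
"(1,2,0,0,0)",1,2
"(3,2,0,0,0)",1,1
"(0,3,0,0,0)",1,1
"(0,0,1,0,0)",7,2
"(1,0,1,0,0)",1,1
"(0,1,1,0,0)",6,1
"(1,1,1,0,0)",1,2
"(0,2,1,0,0)",2,2
"(1,0,2,0,0)",1,2
"(0,1,2,0,0)",5,2
"(0,2,2,0,0)",3,1
"(1,2,3,0,0)",1,1
"(0,1,4,0,0)",1,2
"(0,0,0,1,0)",11,1
"(0,1,0,1,0)",5,2
"(1,1,0,1,0)",1,1
"(0,2,0,1,0)",2,1
"(0,0,1,1,0)",1,1
"(0,1,1,1,0)",2,2
"(0,1,2,1,0)",1,2
"(0,0,0,2,0)",2,1
"(0,1,0,2,0)",1,2
"(0,2,0,2,0)",1,2
"(1,2,0,2,0)",1,2
"(2,2,0,2,0)",1,2
"(1,3,0,2,0)",1,2
"(0,1,1,2,0)",1,2
"(1,2,1,2,0)",1,1
"(1,3,2,2,0)",1,1
"(0,1,0,3,0)",1,2
"(0,1,1,3,0)",1,1
"(2,4,1,4,0)",1,1
"(0,0,0,0,1)",12,2
"(0,1,0,0,1)",3,2
"(1,1,0,0,1)",1,1
"(0,2,0,0,1)",1,1
"(1,2,0,0,1)",1,1
"(0,1,1,0,1)",1,1
"(0,1,2,0,1)",1,1
"(0,0,0,1,1)",1,1
"(1,1,0,1,1)",1,2
"(2,1,0,1,1)",1,2
"(2,2,3,1,1)",1,1
"(0,0,0,2,1)",1,1
"(1,1,0,2,1)",1,2
"(4,2,0,2,1)",1,2
"(0,0,1,2,1)",1,2
"(3,2,2,2,1)",1,2
"(0,0,0,3,1)",1,1
"(0,1,0,3,1)",2,1
"(1,4,3,3,1)",1,2
"(0,4,0,4,1)",1,1
"(0,4,2,4,1)",1,2
"(0,0,0,0,2)",5,2
"(2,2,0,0,2)",1,1
"(0,3,0,0,2)",2,2
"(0,1,1,0,2)",1,2
"(0,2,1,0,2)",1,1
"(3,4,2,0,2)",1,1
"(4,3,3,0,2)",1,1
"(0,1,0,1,2)",1,1
"(0,1,1,1,2)",2,1
"(2,2,1,1,2)",1,2
"(3,3,3,1,2)",1,1
"(0,0,0,2,2)",1,1
"(0,1,0,2,2)",1,2
"(0,2,0,2,2)",1,2
"(0,2,1,2,2)",1,1
"(0,3,3,3,2)",1,2
"(0,2,1,4,2)",1,1
"(1,4,1,4,2)",1,2
"(2,2,2,4,2)",1,1
"(0,0,0,0,3)",1,2
"(3,1,0,3,3)",1,2
"(1,0,0,4,3)",1,1
"(1,3,3,3,4)",1,2
"(2,4,4,3,4)",1,2
"(2,3,4,4,4)",1,1
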